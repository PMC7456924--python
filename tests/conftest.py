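import pytest

import lsukit as lk


@pytest.fixture(scope="session")
def template():
    """Ideal two-helix coiled-coil template sized for the 7-65 span."""
    return lk.build_ideal_template()


@pytest.fixture(scope="session")
def region():
    return lk.DEFAULT_COIL_REGION


@pytest.fixture(scope="session")
def lsu_seqs():
    """The four synthetic LSU-like sequences, keyed by name."""
    seqs, _ = lk.make_lsu_like_sequences(lk.SimulationConfig(seed=0))
    return {s.id: s for s in seqs}
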