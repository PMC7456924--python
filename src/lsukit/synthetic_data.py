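"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all fully deterministic per seed:

* :func:`make_lsu_like_sequences` — four ~100-residue helix-favoring
  sequences carrying the published LSU1-4 leucine landmarks (seven leucines
  conserved in all four: L18, L29, L53, L57, L60, L65, L78; L25 in the
  odd-numbered LSU1/LSU3; L37 and L82 in the even-numbered LSU2/LSU4; L85 in
  LSU1-3) plus the conserved E51/C54 pair.  These stand in for the real LSU
  sequences, which are not bundled here.
* :func:`simulate_tapms` — MaxQuant-style protein-group intensity tables for
  the 4-bait x 4-condition TAP-MS design with planted enriched partners,
  multiplicative log-normal noise, and optional dropout.
* :func:`simulate_network` — interaction networks with planted high-ratio
  hubs wired preferentially to the LSU partner set.

The generators return ground truth alongside the data so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .interactome import InteractionNetwork
from .sequences import ProteinSequence, leucine_profile, write_fasta
from .tapms_scoring import (
    BAITS,
    CONDITIONS,
    CONTROL_BAIT,
    IntensityTable,
    SampleDesign,
)

#: Published leucine landmark positions per LSU protein (1-based).
LSU_LEUCINE_POSITIONS: Mapping[str, frozenset[int]] = {
    "LSU1": frozenset({18, 25, 29, 53, 57, 60, 65, 78, 85}),
    "LSU2": frozenset({18, 29, 37, 53, 57, 60, 65, 78, 82, 85}),
    "LSU3": frozenset({18, 25, 29, 53, 57, 60, 65, 78, 85}),
    "LSU4": frozenset({18, 29, 37, 53, 57, 60, 65, 78, 82}),
}
#: Conserved glutamate/cysteine landmarks shared by all four proteins.
FIXED_RESIDUES: Mapping[int, str] = {1: "M", 51: "E", 54: "C"}

# Helix-favoring background; the charge-free subset is used within the
# landmark windows so no accidental charge pairs or hydrophobic contacts
# perturb the zipper and electrostatic scores.
HELIX_BACKGROUND = "AEKQR"
SAFE_BACKGROUND = "AQ"
LANDMARK_WINDOW = 4


@dataclass(frozen=True)
class SequenceSpec:
    length: int = 100

    def __post_init__(self) -> None:
        if self.length < 100:
            raise ValidationError("sequence length must be >= 100 (landmarks reach 85)")


@dataclass(frozen=True)
class TapmsSpec:
    """TAP-MS simulation parameters.

    ``noise_sd`` is the standard deviation of multiplicative log-normal
    noise in log10 units (matching the scale of the specificity statistic);
    ``fold_enrichment`` multiplies a planted partner's intensity in its own
    bait's probe datasets.  Replicates follow the experimental design: three
    biological replicates for the LSU1 and control lines, two for the
    others.
    """

    n_background: int = 200
    partners_per_bait: int = 3
    fold_enrichment: float = 100.0
    noise_sd: float = 0.2
    dropout: float = 0.0
    base_intensity_range: tuple[float, float] = (1e6, 1e8)
    mw_range_kda: tuple[float, float] = (10.0, 150.0)

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValidationError("fold_enrichment must be > 0")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValidationError("dropout must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    def replicates(self, bait: str) -> int:
        return 3 if bait in ("LSU1-TAP", CONTROL_BAIT) else 2


@dataclass(frozen=True)
class NetworkSpec:
    """Planted-hub network parameters.

    Hubs attach to each partner with probability ``p_hub_partner`` and to
    each background node with ``p_hub_background``; all non-hub, non-bait
    pairs are wired uniformly with ``p_background``.
    """

    n_background: int = 200
    n_partners: int = 20
    n_hubs: int = 5
    p_hub_partner: float = 0.8
    p_hub_background: float = 0.02
    p_background: float = 0.02

    def __post_init__(self) -> None:
        for name in ("p_hub_partner", "p_hub_background", "p_background"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.n_partners >= self.n_background + self.n_partners + self.n_hubs:
            raise ValidationError("partner set must be smaller than the node set")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    sequence: SequenceSpec = field(default_factory=SequenceSpec)
    tapms: TapmsSpec = field(default_factory=TapmsSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {"seed", "sequence", "tapms", "network"}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key: {sorted(unknown)[0]!r}")
        kwargs: dict[str, Any] = {"seed": int(data.get("seed", 0))}
        for section, spec_cls in (
            ("sequence", SequenceSpec),
            ("tapms", TapmsSpec),
            ("network", NetworkSpec),
        ):
            if section in data:
                section_data = dict(data[section])
                valid = set(spec_cls.__dataclass_fields__)
                bad = set(section_data) - valid
                if bad:
                    raise ConfigurationError(
                        f"unknown config key: {section}.{sorted(bad)[0]}"
                    )
                for key in ("base_intensity_range", "mw_range_kda"):
                    if key in section_data:
                        section_data[key] = tuple(section_data[key])
                kwargs[section] = spec_cls(**section_data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def make_lsu_like_sequences(
    config: SimulationConfig | None = None,
) -> tuple[list[ProteinSequence], dict[str, dict]]:
    """Four synthetic LSU-like sequences plus a landmark manifest.

    Each sequence carries leucine exactly at its published landmark set,
    E at 51 and C at 54, with helix-favoring background residues elsewhere
    (charge-free within +/-4 of any landmark).  The background never
    contains leucine, so the leucine profile of each sequence equals its
    landmark set by construction — verified before returning.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    length = config.sequence.length
    seqs: list[ProteinSequence] = []
    manifest: dict[str, dict] = {}
    for name in ("LSU1", "LSU2", "LSU3", "LSU4"):
        leucines = LSU_LEUCINE_POSITIONS[name]
        landmarks = set(leucines) | set(FIXED_RESIDUES)
        near = set()
        for p in landmarks:
            near.update(range(p - LANDMARK_WINDOW, p + LANDMARK_WINDOW + 1))
        chars = []
        for pos in range(1, length + 1):
            if pos in FIXED_RESIDUES:
                chars.append(FIXED_RESIDUES[pos])
            elif pos in leucines:
                chars.append("L")
            elif pos in near:
                chars.append(SAFE_BACKGROUND[rng.integers(len(SAFE_BACKGROUND))])
            else:
                chars.append(HELIX_BACKGROUND[rng.integers(len(HELIX_BACKGROUND))])
        seq = ProteinSequence(id=name, residues="".join(chars))
        assert leucine_profile(seq).positions == leucines
        seqs.append(seq)
        manifest[name] = {
            "leucines": sorted(leucines),
            "glutamate": 51,
            "cysteine": 54,
            "length": length,
        }
    return seqs, manifest


# ---------------------------------------------------------------------------
# TAP-MS tables
# ---------------------------------------------------------------------------


def simulate_tapms(
    config: SimulationConfig | None = None,
) -> tuple[IntensityTable, SampleDesign, dict[str, set[str]]]:
    """Synthetic protein-group table, sample design, and planted truth.

    Background proteins have equal expected intensity in probe and control
    (true ratio 1).  Each bait gets ``partners_per_bait`` planted partners
    whose intensity is multiplied by ``fold_enrichment`` in that bait's
    probe datasets only.  Bait LSU protein groups (with the unresolvable
    LSU2/LSU4 pair as one ambiguous group) are detected only in their own
    lines.  Noise is multiplicative log-normal; dropout zeroes individual
    replicate measurements independently.
    """
    config = config or SimulationConfig()
    spec = config.tapms
    rng = np.random.default_rng(config.seed)

    design_rows = []
    for bait in (*BAITS, CONTROL_BAIT):
        for condition in CONDITIONS:
            for rep in range(1, spec.replicates(bait) + 1):
                design_rows.append(
                    {
                        "sample": f"{bait}.{condition}.r{rep}",
                        "bait": bait,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
    design = SampleDesign(pd.DataFrame(design_rows))
    samples = design.frame

    group_ids = [f"BG{i:04d}" for i in range(spec.n_background)]
    truth: dict[str, set[str]] = {}
    partner_of: dict[str, str] = {}
    for bait in BAITS:
        short = bait.replace("-TAP", "")
        planted = {f"PTN_{short}_{i}" for i in range(1, spec.partners_per_bait + 1)}
        truth[bait] = planted
        for gid in sorted(planted):
            partner_of[gid] = bait
        group_ids.extend(sorted(planted))
    lsu_groups = {"LSU1": ("LSU1-TAP",), "LSU3": ("LSU3-TAP",),
                  "LSU2/LSU4": ("LSU2-TAP", "LSU4-TAP")}
    group_ids.extend(lsu_groups)

    n_groups = len(group_ids)
    lo, hi = spec.base_intensity_range
    base = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n_groups)
    mw = rng.uniform(*spec.mw_range_kda, size=n_groups)

    expected = np.zeros((n_groups, len(samples)))
    for j, row in samples.iterrows():
        bait = row["bait"]
        for i, gid in enumerate(group_ids):
            if gid in lsu_groups:
                expected[i, j] = base[i] if bait in lsu_groups[gid] else 0.0
            elif gid in partner_of:
                factor = spec.fold_enrichment if partner_of[gid] == bait else 1.0
                expected[i, j] = base[i] * factor
            else:
                expected[i, j] = base[i]

    noise = 10 ** rng.normal(0.0, spec.noise_sd, size=expected.shape)
    intensities = expected * noise
    if spec.dropout > 0:
        keep = rng.random(size=intensities.shape) >= spec.dropout
        intensities = intensities * keep

    frame = pd.DataFrame(intensities, columns=list(samples["sample"]))
    frame.insert(0, "mw_kda", mw)
    frame.insert(0, "group_id", group_ids)
    return IntensityTable(frame), design, truth


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def simulate_network(
    config: SimulationConfig | None = None,
) -> tuple[InteractionNetwork, list[str]]:
    """Synthetic LSU interactome with planted hubs; returns (network, hub ids).

    Partners each connect to at least one of the four bait nodes; planted
    hubs wire to partners with high probability and to background with low
    probability; the background (including partner-partner pairs) is wired
    uniformly at random.
    """
    config = config or SimulationConfig()
    spec = config.network
    rng = np.random.default_rng(config.seed)

    baits = [f"LSU{i}" for i in range(1, 5)]
    partners = [f"P{i:03d}" for i in range(1, spec.n_partners + 1)]
    background = [f"N{i:04d}" for i in range(1, spec.n_background + 1)]
    hubs = [f"HUB{i:02d}" for i in range(1, spec.n_hubs + 1)]

    edges: list[tuple[str, str]] = []
    # Each partner interacts with a random nonempty subset of the baits.
    for partner in partners:
        mask = rng.random(len(baits)) < 0.5
        if not mask.any():
            mask[rng.integers(len(baits))] = True
        edges.extend((bait, partner) for bait, m in zip(baits, mask) if m)
    # Planted hubs.
    for hub in hubs:
        mask = rng.random(len(partners)) < spec.p_hub_partner
        edges.extend((hub, p) for p, m in zip(partners, mask) if m)
        mask = rng.random(len(background)) < spec.p_hub_background
        edges.extend((hub, n) for n, m in zip(background, mask) if m)
    # Uniform background wiring among partners and background nodes.
    pool = partners + background
    n_pool = len(pool)
    upper = rng.random((n_pool, n_pool)) < spec.p_background
    for i in range(n_pool):
        for j in range(i + 1, n_pool):
            if upper[i, j]:
                edges.append((pool[i], pool[j]))

    net = InteractionNetwork.from_edges(edges, baits=baits, partners=partners)
    return net, hubs


# ---------------------------------------------------------------------------
# File output (same formats the analysis stages read)
# ---------------------------------------------------------------------------


def write_sequences(config: SimulationConfig, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, _ = make_lsu_like_sequences(config)
    path = out_dir / "lsu_synthetic.fasta"
    write_fasta(seqs, path)
    return path


def write_tapms(config: SimulationConfig, out_dir: str | Path) -> tuple[Path, Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, design, truth = simulate_tapms(config)
    table_path = out_dir / "intensities.tsv"
    design_path = out_dir / "design.tsv"
    truth_path = out_dir / "planted_partners.tsv"
    table.to_tsv(table_path)
    design.to_tsv(design_path)
    pd.DataFrame(
        [(bait, gid) for bait, gids in truth.items() for gid in sorted(gids)],
        columns=["bait", "group_id"],
    ).to_csv(truth_path, sep="\t", index=False)
    return table_path, design_path, truth_path


def write_network(config: SimulationConfig, out_dir: str | Path) -> tuple[Path, Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, hubs = simulate_network(config)
    edges_path = out_dir / "edges.tsv"
    baits_path = out_dir / "baits.txt"
    partners_path = out_dir / "partners.txt"
    with edges_path.open("w") as fh:
        for a, b in sorted(map(sorted, net.graph.edges())):
            fh.write(f"{a}\t{b}\n")
    baits_path.write_text("\n".join(sorted(net.baits)) + "\n")
    partners_path.write_text("\n".join(sorted(net.partners)) + "\n")
    (Path(out_dir) / "planted_hubs.txt").write_text("\n".join(hubs) + "\n")
    return edges_path, baits_path, partners_path
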