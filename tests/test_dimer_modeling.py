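"""Template geometry, threading, zipper scoring, and model selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lsukit as lk
from lsukit.dimer_modeling import (
    MIN_PLACED,
    write_template_pdb,
    zipper_score,
)
from lsukit.errors import DegenerateModelError, ValidationError


def naive_zipper_score(model, cutoff=8.0):
    """Brute-force oracle: all-pairs CB distances between placed leucines."""
    cb = model.template.cb
    leu_a = [
        (slot, cb(0)[slot])
        for slot, aa in zip(model.chain_a.slots, model.chain_a.residues)
        if aa == "L"
    ]
    leu_b = [
        (slot, cb(1)[slot])
        for slot, aa in zip(model.chain_b.slots, model.chain_b.residues)
        if aa == "L"
    ]
    count = 0
    for _, xa in leu_a:
        if any(np.linalg.norm(xa - xb) <= cutoff for _, xb in leu_b):
            count += 1
    for _, xb in leu_b:
        if any(np.linalg.norm(xa - xb) <= cutoff for _, xa in leu_a):
            count += 1
    return count


def random_sequence(rng, length):
    alphabet = "ALEKQR"
    return lk.ProteinSequence(
        f"r{rng.integers(1e9)}", "".join(rng.choice(list(alphabet), size=length))
    )


class TestIdealTemplate:
    def test_slot_count(self, template):
        assert template.n_slots == 59
        assert template.coords.shape == (2, 59, 5, 3)

    def test_ca_trace_spacing(self, template):
        for helix in range(2):
            d = np.linalg.norm(np.diff(template.ca(helix), axis=0), axis=1)
            assert d.min() >= 3.6 and d.max() <= 4.0

    def test_helices_parallel(self, template):
        dot = np.dot(template.axis_vector(0), template.axis_vector(1))
        assert dot > 0

    def test_axis_separation_is_twice_radius(self, template):
        # estimate each local helix axis by averaging CA over one heptad
        # (two helix turns), which cancels the minor-helix offset
        sep = []
        for k in range(template.n_slots - 7):
            a = template.ca(0)[k : k + 7].mean(axis=0)
            b = template.ca(1)[k : k + 7].mean(axis=0)
            sep.append(np.linalg.norm(a[:2] - b[:2]))
        assert np.allclose(sep, 2 * 4.9, atol=0.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_slots": 5},
            {"supercoil_radius": -1.0},
            {"supercoil_pitch": 0.0},
            {"rise_per_residue": -0.1},
        ],
    )
    def test_nonphysical_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            lk.build_ideal_template(**kwargs)


class TestTemplatePdbRoundtrip:
    def test_ideal_roundtrip(self, template, tmp_path):
        path = tmp_path / "template.pdb"
        write_template_pdb(template, path)
        loaded = lk.load_template_pdb(path)
        assert loaded.n_slots == template.n_slots
        assert np.allclose(loaded.coords, template.coords, atol=1e-3)

    def test_missing_chain(self, template, tmp_path):
        path = tmp_path / "template.pdb"
        write_template_pdb(template, path)
        with pytest.raises(ValidationError, match="chain 'X'"):
            lk.load_template_pdb(path, chain_a="X")

    def test_chain_break_detected(self, template, tmp_path):
        broken = template.coords.copy()
        broken[0, 30:, :, 2] += 10.0  # 10 A gap in chain A
        path = tmp_path / "broken.pdb"
        write_template_pdb(
            lk.CoiledCoilTemplate(coords=broken, source="broken"), path
        )
        with pytest.raises(ValidationError, match="chain break"):
            lk.load_template_pdb(path)

    def test_antiparallel_rejected(self, template, tmp_path):
        flipped = template.coords.copy()
        flipped[1] = flipped[1, ::-1]  # reverse slot order of helix B
        path = tmp_path / "anti.pdb"
        write_template_pdb(
            lk.CoiledCoilTemplate(coords=flipped, source="anti"), path
        )
        with pytest.raises(ValidationError, match="antiparallel"):
            lk.load_template_pdb(path)


class TestThreading:
    def test_zero_shift_places_region_start_at_slot_zero(
        self, lsu_seqs, region, template
    ):
        model = lk.thread(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template, lk.RegisterShift(0, 0)
        )
        for chain in (model.chain_a, model.chain_b):
            assert chain.slots[0] == 0
            assert chain.res_positions[0] == region.start
            assert len(chain) == len(region)

    def test_positive_shift_drops_overhang(self, lsu_seqs, region, template):
        model = lk.thread(
            lsu_seqs["LSU1"], lsu_seqs["LSU1"], region, template, lk.RegisterShift(2, 0)
        )
        assert model.chain_a.slots[0] == 2
        assert len(model.chain_a) == len(region) - 2
        assert model.chain_a.res_positions[-1] == region.end - 2
        assert len(model.chain_b) == len(region)

    def test_extreme_shift_is_degenerate(self, lsu_seqs, region, template):
        with pytest.raises(DegenerateModelError):
            lk.thread(
                lsu_seqs["LSU1"],
                lsu_seqs["LSU1"],
                region,
                template,
                lk.RegisterShift(-(len(region) - MIN_PLACED + 1), 0),
            )

    def test_diagonal_shift_congruent_to_origin(self, lsu_seqs, region, template):
        """For identical sequences, shift (s, s) relabels slots of (0, 0)."""
        seq = lsu_seqs["LSU3"]
        base = lk.thread(seq, seq, region, template, lk.RegisterShift(0, 0))
        shifted = lk.thread(seq, seq, region, template, lk.RegisterShift(3, 3))
        # same residues occupy slots offset by 3
        n = len(shifted.chain_a)
        assert np.array_equal(shifted.chain_a.slots, base.chain_a.slots[:n] + 3)
        assert shifted.chain_a.residues == base.chain_a.residues[:n]


class TestZipperScore:
    def test_no_leucines_scores_zero(self, region, template):
        seq = lk.ProteinSequence("a", "A" * 70)
        model = lk.thread(seq, seq, region, template, lk.RegisterShift(0, 0))
        assert zipper_score(model) == 0

    def test_polyalanine_vs_polyleucine_zero(self, region, template):
        a = lk.ProteinSequence("a", "A" * 70)
        b = lk.ProteinSequence("b", "L" * 70)
        model = lk.thread(a, b, region, template, lk.RegisterShift(0, 0))
        assert zipper_score(model) == 0

    def test_heptad_leucines_match_bruteforce(self, template):
        # leucines at every a and d position of a heptad repeat
        residues = "LAALAAA" * 10
        seq = lk.ProteinSequence("hep", residues)
        region = lk.CoilRegion(1, 59)
        model = lk.thread(seq, seq, region, template, lk.RegisterShift(0, 0))
        score = zipper_score(model)
        assert score == naive_zipper_score(model)
        assert score > 0

    @given(seed=st.integers(0, 10_000), sa=st.integers(-5, 5), sb=st.integers(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_bruteforce_oracle(self, template, seed, sa, sb):
        rng = np.random.default_rng(seed)
        region = lk.CoilRegion(1, 40)
        seq_a = random_sequence(rng, 40)
        seq_b = random_sequence(rng, 40)
        model = lk.thread(seq_a, seq_b, region, template, lk.RegisterShift(sa, sb))
        assert zipper_score(model) == naive_zipper_score(model)

    def test_score_bounded_by_placed_leucines(self, lsu_seqs, region, template):
        model = lk.thread(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template, lk.RegisterShift(0, 0)
        )
        bound = model.chain_a.leucine_slots().size + model.chain_b.leucine_slots().size
        assert 0 <= zipper_score(model) <= bound

    def test_leucine_to_alanine_never_increases(self, lsu_seqs, region, template):
        seq = lsu_seqs["LSU1"]
        for pos in sorted(lk.leucine_profile(seq).positions):
            mutant = lk.ProteinSequence(
                "mut", seq.residues[: pos - 1] + "A" + seq.residues[pos:]
            )
            for shift in (lk.RegisterShift(0, 0), lk.RegisterShift(4, -2)):
                wild = zipper_score(lk.thread(seq, seq, region, template, shift))
                less = zipper_score(lk.thread(mutant, mutant, region, template, shift))
                assert less <= wild


class TestShiftGrid:
    @pytest.mark.parametrize("half_width,expected", [(0, 1), (1, 9), (25, 2601)])
    def test_grid_cardinality(self, lsu_seqs, region, template, half_width, expected):
        grid = lk.scan_register_shifts(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template, half_width=half_width
        )
        assert grid.n_models == expected
        assert grid.scores.shape == (2 * half_width + 1,) * 2

    def test_grid_matches_thread_and_score(self, lsu_seqs, region, template):
        grid = lk.scan_register_shifts(
            lsu_seqs["LSU1"], lsu_seqs["LSU4"], region, template, half_width=3
        )
        for sa, sb in itertools.product(range(-3, 4), repeat=2):
            model = lk.thread(
                lsu_seqs["LSU1"],
                lsu_seqs["LSU4"],
                region,
                template,
                lk.RegisterShift(sa, sb),
            )
            assert grid.score_at(sa, sb) == zipper_score(model)

    def test_swap_symmetry_on_ideal_template(self, lsu_seqs, region, template):
        ab = lk.scan_register_shifts(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template, half_width=4
        )
        ba = lk.scan_register_shifts(
            lsu_seqs["LSU2"], lsu_seqs["LSU1"], region, template, half_width=4
        )
        assert np.array_equal(ab.scores, ba.scores.T)

    def test_translation_invariance_without_truncation(self, template):
        # leucines well inside both regions; matched shifts place the same
        # residues on the same slots
        seq = lk.ProteinSequence("t", "A" * 20 + "LAALAAALAA" + "A" * 30)
        r1, r2 = lk.CoilRegion(10, 45), lk.CoilRegion(12, 47)
        g1 = lk.scan_register_shifts(seq, seq, r1, template, half_width=5)
        g2 = lk.scan_register_shifts(seq, seq, r2, template, half_width=5)
        for sa, sb in ((0, 0), (2, -1), (-2, 3)):
            # residue p sits at slot p - start + shift, so start + 2 with
            # shift + 2 places the same residues on the same slots
            assert g2.score_at(sa + 2, sb + 2) == g1.score_at(sa, sb)

    def test_degenerate_registers_are_excluded(self, lsu_seqs, template):
        region = lk.CoilRegion(7, 65)
        grid = lk.scan_register_shifts(
            lsu_seqs["LSU1"], lsu_seqs["LSU1"], region, template, half_width=60
        )
        assert np.isneginf(grid.scores[0, 0])  # shift -60 leaves nothing placed
        best = grid.best_score()
        assert np.isfinite(best)

    def test_grid_tsv_export(self, lsu_seqs, region, template, tmp_path):
        import pandas as pd

        grid = lk.scan_register_shifts(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template, half_width=2
        )
        path = tmp_path / "grid.tsv"
        grid.to_tsv(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        assert frame.shape == (5, 5)
        assert list(frame.columns) == ["-2", "-1", "0", "1", "2"]


class TestSelectBest:
    def test_selection_attains_grid_maximum(self, lsu_seqs, region, template):
        grid = lk.scan_register_shifts(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template
        )
        best = lk.select_best(grid, lsu_seqs["LSU1"], lsu_seqs["LSU2"])
        assert best[0].zipper_score == grid.best_score()
        deltas = [abs(m.delta_shift) for m in best]
        assert deltas == sorted(deltas)

    def test_homodimer_tie_set_swap_symmetric(self, lsu_seqs, region, template):
        grid = lk.scan_register_shifts(
            lsu_seqs["LSU2"], lsu_seqs["LSU2"], region, template
        )
        ties = {
            (m.shift.shift_a, m.shift.shift_b)
            for m in lk.select_best(grid, lsu_seqs["LSU2"], lsu_seqs["LSU2"])
        }
        assert ties == {(b, a) for a, b in ties}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_equals_exhaustive_argmax(self, template, seed):
        rng = np.random.default_rng(seed)
        region = lk.CoilRegion(1, 30)
        seq_a, seq_b = random_sequence(rng, 30), random_sequence(rng, 30)
        grid = lk.scan_register_shifts(seq_a, seq_b, region, template, half_width=3)
        # independent brute force over all registers
        best_score, best_shifts = -1, set()
        for sa, sb in itertools.product(range(-3, 4), repeat=2):
            model = lk.thread(seq_a, seq_b, region, template, lk.RegisterShift(sa, sb))
            score = naive_zipper_score(model)
            if score > best_score:
                best_score, best_shifts = score, {(sa, sb)}
            elif score == best_score:
                best_shifts.add((sa, sb))
        selected = lk.select_best(grid, seq_a, seq_b)
        assert selected[0].zipper_score == best_score
        assert {(m.shift.shift_a, m.shift.shift_b) for m in selected} == best_shifts

    def test_all_degenerate_grid_errors(self, template):
        all_degenerate = lk.ShiftGrid(
            scores=np.full((3, 3), -np.inf),
            half_width=1,
            id_a="a",
            id_b="b",
            region=lk.CoilRegion(7, 65),
            cutoff=8.0,
            template=template,
        )
        with pytest.raises(DegenerateModelError):
            all_degenerate.best_score()


class TestEnergyProxy:
    def test_chemically_inert_interface_is_zero(self, region, template):
        seq = lk.ProteinSequence("a", "A" * 70)
        model = lk.thread(seq, seq, region, template, lk.RegisterShift(0, 0))
        assert lk.interface_energy_proxy(model) == 0.0

    def test_single_leu_leu_contact_lowers_by_one(self, region, template):
        plain = lk.ProteinSequence("a", "A" * 70)
        base = lk.thread(plain, plain, region, template, lk.RegisterShift(0, 0))
        # find a slot pair in contact and place one leucine on each chain there
        from scipy.spatial.distance import cdist

        contact = cdist(template.cb(0), template.cb(1)) <= 8.0
        slot_a, slot_b = map(int, np.argwhere(contact)[0])
        res_a = region.start + slot_a
        res_b = region.start + slot_b
        with_leu = lk.thread(
            lk.ProteinSequence("a", plain.residues[: res_a - 1] + "L" + plain.residues[res_a:]),
            lk.ProteinSequence("b", plain.residues[: res_b - 1] + "L" + plain.residues[res_b:]),
            region,
            template,
            lk.RegisterShift(0, 0),
        )
        assert lk.interface_energy_proxy(with_leu) == lk.interface_energy_proxy(base) - 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_bruteforce_summation(self, template, seed):
        rng = np.random.default_rng(seed)
        alphabet = list("ALEKRDQ")
        region = lk.CoilRegion(1, 30)
        seq_a = lk.ProteinSequence("a", "".join(rng.choice(alphabet, 30)))
        seq_b = lk.ProteinSequence("b", "".join(rng.choice(alphabet, 30)))
        model = lk.thread(seq_a, seq_b, region, template, lk.RegisterShift(0, 0))
        hydrophobic, acidic, basic = set("LIVMF"), set("DE"), set("KR")
        expected = 0.0
        for i, slot_a in enumerate(model.chain_a.slots):
            for j, slot_b in enumerate(model.chain_b.slots):
                d = np.linalg.norm(template.cb(0)[slot_a] - template.cb(1)[slot_b])
                if d > 8.0:
                    continue
                aa1 = model.chain_a.residues[i]
                aa2 = model.chain_b.residues[j]
                if aa1 in hydrophobic and aa2 in hydrophobic:
                    expected -= 1.0
                elif (aa1 in acidic and aa2 in acidic) or (aa1 in basic and aa2 in basic):
                    expected += 0.5
                elif (aa1 in acidic and aa2 in basic) or (aa1 in basic and aa2 in acidic):
                    expected -= 0.5
        assert lk.interface_energy_proxy(model) == pytest.approx(expected)


class TestModelPdb:
    def test_roundtrip_preserves_coordinates_and_numbering(
        self, lsu_seqs, region, template, tmp_path
    ):
        model = lk.thread(
            lsu_seqs["LSU1"], lsu_seqs["LSU2"], region, template, lk.RegisterShift(0, 0)
        )
        path = tmp_path / "model.pdb"
        lk.write_model_pdb(model, path)
        loaded = lk.load_template_pdb(path)
        assert np.allclose(loaded.ca(0), template.ca(0)[model.chain_a.slots], atol=1e-3)

        from biotite.structure.io.pdb import PDBFile

        array = PDBFile.read(str(path)).get_structure(model=1)
        res_a = np.unique(array.res_id[array.chain_id == "A"])
        assert res_a.min() == region.start and res_a.max() == region.end

    def test_empty_model_rejected(self, lsu_seqs, region, template, tmp_path):
        from lsukit.dimer_modeling import ChainPlacement, DimerModel

        empty = ChainPlacement(
            slots=np.array([], dtype=int), res_positions=np.array([], dtype=int), residues=""
        )
        model = DimerModel(
            id_a="a", id_b="b", shift=lk.RegisterShift(0, 0), chain_a=empty,
            chain_b=empty, template=template, region=region,
        )
        with pytest.raises(ValidationError):
            lk.write_model_pdb(model, tmp_path / "empty.pdb")


def test_all_sixteen_ordered_pairs_modelable(lsu_seqs, region, template):
    reports = lk.scan_all_pairs(
        list(lsu_seqs.values()), region, template, half_width=2
    )
    assert len(reports) == 16
    assert set(reports) == set(itertools.product(lsu_seqs, repeat=2))
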