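"""Parallel coiled-coil dimer models scored by leucine-zipper contacts.

The workflow mirrors template-based register scanning for two-stranded
coiled coils:

1. a two-helix parallel template provides per-slot backbone coordinates and a
   side-chain anchor (CB) per slot — either an ideal Crick-parameterized
   backbone (:func:`build_ideal_template`) or one loaded from a two-chain PDB
   file (:func:`load_template_pdb`);
2. a pair of sequences is threaded onto the template at an integer register
   shift per helix, with no gaps permitted and overhanging residues dropped
   (:func:`thread`);
3. each threaded model is scored by the number of leucine side chains whose
   anchor lies within a distance cutoff of a leucine anchor on the opposite
   chain (:func:`zipper_score`) — the leucine-zipper contact count;
4. the full shift x shift grid is enumerated (:func:`scan_register_shifts`,
   default half-width 25, i.e. 51 x 51 = 2,601 models per pair) and the
   best-scoring models are selected (:func:`select_best`).

A qualitative mutation-effect predictor combines the change in best zipper
score with an intra-helical i, i+/-3 / i, i+/-4 charge-pair term
(:func:`predict_mutation_effect`).  The crude contact-count interface energy
(:func:`interface_energy_proxy`) is a qualitative proxy only; free-energy
estimates for these dimers are known to be unreliable at this fragment scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from Bio.SeqUtils import seq3

from .errors import DegenerateModelError, InputError, ValidationError
from .sequences import CoilRegion, ProteinSequence

logger = logging.getLogger(__name__)

# Residue classes for contact scoring
HYDROPHOBIC = frozenset("LIVMF")
ACIDIC = frozenset("DE")
BASIC = frozenset("KR")

#: Default side-chain-anchor contact cutoff (Angstrom).  CB-CB distances of
#: core-packed leucines in two-stranded coiled coils fall well below this,
#: while outward-facing pairs do not.
DEFAULT_CUTOFF = 8.0
#: Default register-scan half-width: shifts -25..+25 per helix, 51 values,
#: about half a supercoil turn.
DEFAULT_HALF_WIDTH = 25
#: Minimum residues that must remain placed on each helix for a model to count.
MIN_PLACED = 7

ATOM_NAMES = ("N", "CA", "C", "O", "CB")
_CB_INDEX = ATOM_NAMES.index("CB")
_CA_INDEX = ATOM_NAMES.index("CA")


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoiledCoilTemplate:
    """Backbone + side-chain-anchor coordinates for two parallel helices.

    ``coords`` has shape (2, n_slots, 5, 3) with atoms ordered N, CA, C, O,
    CB, in Angstrom.  Slot k of helix 0 packs against slots near k of
    helix 1.
    """

    coords: np.ndarray
    source: str = "ideal"

    @property
    def n_slots(self) -> int:
        return self.coords.shape[1]

    def ca(self, helix: int) -> np.ndarray:
        return self.coords[helix, :, _CA_INDEX, :]

    def cb(self, helix: int) -> np.ndarray:
        return self.coords[helix, :, _CB_INDEX, :]

    def axis_vector(self, helix: int) -> np.ndarray:
        ca = self.ca(helix)
        return ca[-1] - ca[0]


def build_ideal_template(
    n_slots: int = 59,
    supercoil_radius: float = 4.9,
    rise_per_residue: float = 1.51,
    residues_per_turn: float = 3.62,
    supercoil_pitch: float = 150.0,
) -> CoiledCoilTemplate:
    """Ideal two-stranded left-handed coiled-coil backbone (Crick geometry).

    Both helices wind on a common superhelical axis (z), 180 degrees apart in
    superhelical phase, so the template is parallel by construction.  The
    defaults are standard literature values for two-stranded left-handed
    coiled coils; with them, consecutive CA-CA distances come out near
    3.85 A and the side-chain anchor of slot 0 points at the partner helix.

    Parameters are in Angstrom (radii, rise, pitch) or residues/turn.
    """
    if n_slots < MIN_PLACED:
        raise ValidationError(f"n_slots must be >= {MIN_PLACED}, got {n_slots}")
    for name, value in (
        ("supercoil_radius", supercoil_radius),
        ("rise_per_residue", rise_per_residue),
        ("residues_per_turn", residues_per_turn),
        ("supercoil_pitch", supercoil_pitch),
    ):
        if value <= 0:
            raise ValidationError(f"{name} must be positive, got {value}")

    # Left-handed supercoil: the helix axis rotates by w0 < 0 per residue.
    w0 = -2.0 * math.pi * rise_per_residue / supercoil_pitch
    # Right-handed alpha-helix twist per residue.
    w1 = 2.0 * math.pi / residues_per_turn
    # Side-chain phase relative to the rotating outward normal; w1 - w0
    # ~ 103 deg/residue, i.e. near-exact heptad periodicity.
    w_rel = w1 - w0
    # Pitch angle: the minor-helix plane is perpendicular to the supercoiled
    # axis curve, not to z.  Without this tilt the CA trace is uneven.
    hyp = math.hypot(supercoil_radius * w0, rise_per_residue)
    sin_alpha = supercoil_radius * w0 / hyp
    cos_alpha = rise_per_residue / hyp

    def place(helix: int, t: np.ndarray, radius: float, psi_off: float) -> np.ndarray:
        theta = w0 * t + (0.0 if helix == 0 else math.pi)
        zeros = np.zeros_like(theta)
        normal = np.stack([np.cos(theta), np.sin(theta), zeros], axis=-1)
        binormal = np.stack([-np.sin(theta), np.cos(theta), zeros], axis=-1)
        tilted = cos_alpha * binormal
        tilted[..., 2] = -sin_alpha
        axis = supercoil_radius * normal
        axis[..., 2] = rise_per_residue * t
        # psi = pi at t = 0: the anchor points inward, toward the partner.
        psi = math.pi + w_rel * t + psi_off
        return axis + radius * (
            np.cos(psi)[..., None] * normal + np.sin(psi)[..., None] * tilted
        )

    t = np.arange(n_slots, dtype=float)
    coords = np.empty((2, n_slots, len(ATOM_NAMES), 3))
    # (parameter offset along the helix, radius from the local axis, extra
    # phase) per atom; idealized alpha-helix internal geometry.
    atom_geometry = {
        "N": (-0.36, 1.60, 0.0),
        "CA": (0.0, 2.26, 0.0),
        "C": (0.44, 1.70, 0.0),
        "O": (0.72, 2.20, 0.0),
        "CB": (0.0, 3.43, -0.20),
    }
    for helix in range(2):
        for a, name in enumerate(ATOM_NAMES):
            dt, radius, psi_off = atom_geometry[name]
            coords[helix, :, a, :] = place(helix, t + dt, radius, psi_off)

    template = CoiledCoilTemplate(coords=coords, source="ideal")
    _check_ca_trace(template)
    return template


def _check_ca_trace(template: CoiledCoilTemplate, lo: float = 3.6, hi: float = 4.0):
    for helix in range(2):
        d = np.linalg.norm(np.diff(template.ca(helix), axis=0), axis=1)
        if d.size and not ((d >= lo) & (d <= hi)).all():
            raise ValidationError(
                f"helix {helix}: consecutive CA-CA distances outside "
                f"[{lo}, {hi}] A (min {d.min():.2f}, max {d.max():.2f})"
            )


def _reconstruct_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Approximate CB position from backbone N, CA, C (tetrahedral geometry)."""
    u = ca - n
    v = ca - c
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    bisector = u + v
    bisector /= np.linalg.norm(bisector, axis=-1, keepdims=True)
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal, axis=-1, keepdims=True)
    return ca + 1.53 * (0.577 * bisector + 0.817 * normal)


def load_template_pdb(
    path: str | Path, chain_a: str = "A", chain_b: str = "B"
) -> CoiledCoilTemplate:
    """Build a template from a two-chain alpha-helical PDB file.

    Missing CB atoms (e.g. glycine) are reconstructed from backbone geometry.
    Chains of unequal usable length are truncated to the common length with a
    warning; antiparallel chains and chain breaks (CA-CA > 4.5 A) are errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"PDB file not found: {path}")
    structure = PDBFile.read(str(path)).get_structure(model=1)
    structure = structure[struc.filter_amino_acids(structure)]

    per_chain = []
    for chain_id in (chain_a, chain_b):
        chain = structure[structure.chain_id == chain_id]
        if chain.array_length() == 0:
            raise ValidationError(f"chain {chain_id!r} not found in {path}")
        res_ids = np.unique(chain.res_id)
        slots = []
        for res_id in res_ids:
            res = chain[chain.res_id == res_id]
            atoms = {}
            for name in ("N", "CA", "C", "O", "CB"):
                sel = res[res.atom_name == name]
                if sel.array_length():
                    atoms[name] = sel.coord[0]
            if not all(n in atoms for n in ("N", "CA", "C", "O")):
                continue  # skip incomplete residues at termini
            if "CB" not in atoms:
                atoms["CB"] = _reconstruct_cb(atoms["N"], atoms["CA"], atoms["C"])
            slots.append([atoms[n] for n in ATOM_NAMES])
        if len(slots) < MIN_PLACED:
            raise ValidationError(
                f"chain {chain_id!r}: fewer than {MIN_PLACED} usable residues"
            )
        per_chain.append(np.asarray(slots))

    n_common = min(arr.shape[0] for arr in per_chain)
    if len({arr.shape[0] for arr in per_chain}) > 1:
        logger.warning(
            "template chains have unequal lengths (%s); truncating to %d slots",
            [arr.shape[0] for arr in per_chain],
            n_common,
        )
        per_chain = [arr[:n_common] for arr in per_chain]

    coords = np.stack(per_chain)
    template = CoiledCoilTemplate(coords=coords, source=str(path))

    for helix in range(2):
        ca = template.ca(helix)
        gaps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        breaks = np.nonzero(gaps > 4.5)[0]
        if breaks.size:
            raise ValidationError(
                f"chain {(chain_a, chain_b)[helix]!r} has a chain break after "
                f"slot {int(breaks[0])} (CA-CA {gaps[breaks[0]]:.2f} A)"
            )
    if float(np.dot(template.axis_vector(0), template.axis_vector(1))) <= 0:
        raise ValidationError(
            "template chains are antiparallel; parallel dimers are required"
        )
    return template


def write_template_pdb(template: CoiledCoilTemplate, path: str | Path) -> None:
    """Write the bare template as a two-chain poly-alanine PDB file."""
    n = template.n_slots
    placements = [
        ChainPlacement(
            slots=np.arange(n), res_positions=np.arange(1, n + 1), residues="A" * n
        )
        for _ in range(2)
    ]
    _write_pdb(template, placements[0], placements[1], path)


# ---------------------------------------------------------------------------
# Threading and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegisterShift:
    """Integer register offset per helix; |shift| <= the grid half-width."""

    shift_a: int
    shift_b: int

    @property
    def delta(self) -> int:
        return self.shift_a - self.shift_b


@dataclass(frozen=True)
class ChainPlacement:
    """Residues of one chain placed on template slots (gap-free segment)."""

    slots: np.ndarray  # template slot per placed residue
    res_positions: np.ndarray  # original 1-based residue numbers
    residues: str  # one-letter codes, same order

    def __len__(self) -> int:
        return len(self.slots)

    def leucine_slots(self) -> np.ndarray:
        mask = np.frombuffer(self.residues.encode(), dtype=np.uint8) == ord("L")
        return self.slots[mask]


@dataclass(frozen=True)
class DimerModel:
    """One threaded dimer at a fixed (shift_a, shift_b) register."""

    id_a: str
    id_b: str
    shift: RegisterShift
    chain_a: ChainPlacement
    chain_b: ChainPlacement
    template: CoiledCoilTemplate = field(repr=False)
    region: CoilRegion
    zipper_score: int | None = None
    energy_proxy: float | None = None

    @property
    def delta_shift(self) -> int:
        return self.shift.delta


def thread(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    region: CoilRegion,
    template: CoiledCoilTemplate,
    shift: RegisterShift,
) -> DimerModel:
    """Place ``region`` of each sequence on the template at ``shift``.

    Residue ``region.start + k`` of a chain occupies template slot
    ``k + shift`` of its helix; residues shifted past either template end are
    dropped (overhang truncation), and no gaps are ever introduced.  A shift
    leaving fewer than 7 residues on either helix raises
    :class:`DegenerateModelError`.
    """
    region.validate_for(seq_a)
    region.validate_for(seq_b)
    chains = []
    for seq, s in ((seq_a, shift.shift_a), (seq_b, shift.shift_b)):
        k = np.arange(len(region))
        slots = k + s
        mask = (slots >= 0) & (slots < template.n_slots)
        if int(mask.sum()) < MIN_PLACED:
            raise DegenerateModelError(
                f"shift {s} leaves {int(mask.sum())} residues of {seq.id!r} on "
                f"the template (minimum {MIN_PLACED})"
            )
        positions = np.asarray(region.positions())[mask]
        residues = "".join(seq.residues[p - 1] for p in positions)
        chains.append(
            ChainPlacement(slots=slots[mask], res_positions=positions, residues=residues)
        )
    return DimerModel(
        id_a=seq_a.id,
        id_b=seq_b.id,
        shift=shift,
        chain_a=chains[0],
        chain_b=chains[1],
        template=template,
        region=region,
    )


def zipper_score(model: DimerModel, cutoff: float = DEFAULT_CUTOFF) -> int:
    """Number of leucine side chains engaged in intermolecular Leu-Leu contacts.

    A leucine counts (once) if its side-chain anchor lies within ``cutoff`` of
    the anchor of at least one leucine on the opposite chain; both chains
    contribute, so the score is bounded by the number of placed leucines.
    """
    slots_a = model.chain_a.leucine_slots()
    slots_b = model.chain_b.leucine_slots()
    if slots_a.size == 0 or slots_b.size == 0:
        return 0
    d = cdist(model.template.cb(0)[slots_a], model.template.cb(1)[slots_b])
    contact = d <= cutoff
    return int(contact.any(axis=1).sum() + contact.any(axis=0).sum())


@dataclass(frozen=True)
class ShiftGrid:
    """Zipper scores over the full (shift_a, shift_b) register grid.

    ``scores[i, j]`` holds the score at shift_a = shifts[i],
    shift_b = shifts[j]; degenerate registers carry ``-inf`` and are never
    selected.
    """

    scores: np.ndarray
    half_width: int
    id_a: str
    id_b: str
    region: CoilRegion
    cutoff: float
    template: CoiledCoilTemplate = field(repr=False)

    @property
    def shifts(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width + 1)

    @property
    def n_models(self) -> int:
        return int(self.scores.size)

    def score_at(self, shift_a: int, shift_b: int) -> float:
        w = self.half_width
        return float(self.scores[shift_a + w, shift_b + w])

    def best_score(self) -> int:
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size == 0:
            raise DegenerateModelError(
                f"all {self.n_models} registers of {self.id_a}-{self.id_b} "
                "are degenerate"
            )
        return int(finite.max())

    def to_tsv(self, path: str | Path) -> None:
        """Export the score matrix as TSV (rows shift_a, columns shift_b)."""
        import pandas as pd

        frame = pd.DataFrame(self.scores, index=self.shifts, columns=self.shifts)
        frame.index.name = "shiftA\\shiftB"
        frame.to_csv(path, sep="\t")


def scan_register_shifts(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    region: CoilRegion,
    template: CoiledCoilTemplate,
    half_width: int = DEFAULT_HALF_WIDTH,
    cutoff: float = DEFAULT_CUTOFF,
) -> ShiftGrid:
    """Score every register combination; (2*half_width + 1)^2 models total.

    Equivalent to calling :func:`thread` + :func:`zipper_score` on each
    register, but the slot-to-slot contact matrix is precomputed once.
    """
    if half_width < 0:
        raise ValidationError(f"half_width must be >= 0, got {half_width}")
    region.validate_for(seq_a)
    region.validate_for(seq_b)
    n = template.n_slots
    length = len(region)
    contact = cdist(template.cb(0), template.cb(1)) <= cutoff

    # Leucine offsets within the coil region, per chain.
    leu_off = []
    for seq in (seq_a, seq_b):
        segment = seq.residues[region.start - 1 : region.end]
        leu_off.append(np.nonzero(np.frombuffer(segment.encode(), np.uint8) == ord("L"))[0])

    shifts = np.arange(-half_width, half_width + 1)
    scores = np.full((shifts.size, shifts.size), -np.inf)

    def placed_count(s: int) -> int:
        return max(0, min(length - 1 + s, n - 1) - max(0, s) + 1)

    ok = np.array([placed_count(s) >= MIN_PLACED for s in shifts])
    leu_slots = []
    for off in leu_off:
        per_shift = []
        for s in shifts:
            slots = off + s
            per_shift.append(slots[(slots >= 0) & (slots < n)])
        leu_slots.append(per_shift)

    for i, sa in enumerate(shifts):
        if not ok[i]:
            continue
        a_slots = leu_slots[0][i]
        for j, sb in enumerate(shifts):
            if not ok[j]:
                continue
            b_slots = leu_slots[1][j]
            if a_slots.size == 0 or b_slots.size == 0:
                scores[i, j] = 0
                continue
            sub = contact[np.ix_(a_slots, b_slots)]
            scores[i, j] = sub.any(axis=1).sum() + sub.any(axis=0).sum()

    return ShiftGrid(
        scores=scores,
        half_width=half_width,
        id_a=seq_a.id,
        id_b=seq_b.id,
        region=region,
        cutoff=cutoff,
        template=template,
    )


def select_best(
    grid: ShiftGrid, seq_a: ProteinSequence, seq_b: ProteinSequence
) -> list[DimerModel]:
    """All models attaining the maximal zipper score.

    Ordered by (|delta_shift| ascending, shift_a ascending, shift_b
    ascending), so the most "symmetric" optimal register comes first.  The
    set of optimal delta_shift values is the register-shift series of the
    pair (see :func:`optimal_delta_shifts`).
    """
    best = grid.best_score()
    w = grid.half_width
    ties = [
        (int(sa - w), int(sb - w))
        for sa, sb in zip(*np.nonzero(grid.scores == best))
    ]
    ties.sort(key=lambda t: (abs(t[0] - t[1]), t[0], t[1]))
    models = []
    for sa, sb in ties:
        model = thread(seq_a, seq_b, grid.region, grid.template, RegisterShift(sa, sb))
        models.append(replace(model, zipper_score=best))
    return models


def optimal_delta_shifts(grid: ShiftGrid) -> list[int]:
    """Sorted distinct delta_shift (shift_a - shift_b) values at the optimum."""
    best = grid.best_score()
    w = grid.half_width
    deltas = {
        int(sa) - int(sb)
        for sa, sb in zip(*np.nonzero(grid.scores == best))
    }
    return sorted(deltas, key=lambda d: (abs(d), d))


def scan_all_pairs(
    seqs: list[ProteinSequence],
    region: CoilRegion,
    template: CoiledCoilTemplate,
    half_width: int = DEFAULT_HALF_WIDTH,
    cutoff: float = DEFAULT_CUTOFF,
) -> dict[tuple[str, str], dict]:
    """Register scans for every ordered pair (including homodimers).

    Four monomers give the full 4 x 4 = 16 homo/heterodimer panel.  Returns a
    JSON-serializable report per pair: best score, optimal shifts, the
    delta-shift series, and the grid size.
    """
    reports: dict[tuple[str, str], dict] = {}
    for seq_a, seq_b in itertools.product(seqs, repeat=2):
        grid = scan_register_shifts(seq_a, seq_b, region, template, half_width, cutoff)
        best_models = select_best(grid, seq_a, seq_b)
        reports[(seq_a.id, seq_b.id)] = {
            "pair": [seq_a.id, seq_b.id],
            "n_models": grid.n_models,
            "best_zipper_score": grid.best_score(),
            "optimal_shifts": [
                [m.shift.shift_a, m.shift.shift_b] for m in best_models
            ],
            "delta_shift_series": optimal_delta_shifts(grid),
            "grid": grid,
        }
    return reports


# ---------------------------------------------------------------------------
# Interface energy proxy
# ---------------------------------------------------------------------------


def _pair_energy(aa1: str, aa2: str) -> float:
    if aa1 in HYDROPHOBIC and aa2 in HYDROPHOBIC:
        return -1.0
    charged1 = aa1 in ACIDIC or aa1 in BASIC
    charged2 = aa2 in ACIDIC or aa2 in BASIC
    if charged1 and charged2:
        same = (aa1 in ACIDIC) == (aa2 in ACIDIC)
        return 0.5 if same else -0.5
    return 0.0


def interface_energy_proxy(model: DimerModel, cutoff: float = DEFAULT_CUTOFF) -> float:
    """Qualitative interface score; lower is more favorable.

    Sums -1 per intermolecular hydrophobic (L/I/V/M/F) anchor contact,
    +0.5 per like-charged and -0.5 per opposite-charged anchor contact within
    ``cutoff``.  This is a deterministic contact-count proxy, not a physical
    free energy, and is meant only for qualitative ranking.
    """
    cb_a = model.template.cb(0)[model.chain_a.slots]
    cb_b = model.template.cb(1)[model.chain_b.slots]
    if cb_a.size == 0 or cb_b.size == 0:
        return 0.0
    contact = cdist(cb_a, cb_b) <= cutoff
    total = 0.0
    for i, j in zip(*np.nonzero(contact)):
        total += _pair_energy(model.chain_a.residues[i], model.chain_b.residues[j])
    return total


# ---------------------------------------------------------------------------
# Mutation-effect prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mutation:
    """Point substitution, e.g. ``Mutation.parse("C54E")``."""

    position: int
    from_aa: str
    to_aa: str

    @classmethod
    def parse(cls, text: str) -> "Mutation":
        import re

        match = re.fullmatch(r"([A-Za-z])(\d+)([A-Za-z])", text.strip())
        if match is None:
            raise ValidationError(f"cannot parse mutation {text!r} (expected e.g. C54E)")
        return cls(
            position=int(match.group(2)),
            from_aa=match.group(1).upper(),
            to_aa=match.group(3).upper(),
        )

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class MutationEffect:
    """Qualitative verdict with its two score components.

    ``zipper_delta`` is (best mutant zipper score) - (best wild-type zipper
    score) over the full register grid; ``electro_delta`` counts intra-helical
    charge pairs at (i, i+/-3) and (i, i+/-4) created or removed by the
    substitution (positive = repulsive pairs gained).  The verdict rule:
    destabilizing if zipper_delta < 0 or electro_delta > 0, stabilizing if
    zipper_delta > 0 or electro_delta < 0, neutral otherwise; the zipper term
    dominates when the two disagree.
    """

    verdict: str  # stabilizing | neutral | destabilizing
    zipper_delta: int
    electro_delta: float
    context: str  # homodimer | heterodimer


def apply_mutation(seq: ProteinSequence, mutation: Mutation) -> ProteinSequence:
    wt = seq.residue(mutation.position)
    if wt != mutation.from_aa:
        raise ValidationError(
            f"mutation {mutation}: {seq.id!r} has {wt!r} at position "
            f"{mutation.position}, not {mutation.from_aa!r}"
        )
    residues = (
        seq.residues[: mutation.position - 1]
        + mutation.to_aa
        + seq.residues[mutation.position :]
    )
    return ProteinSequence(id=f"{seq.id}_{mutation}", residues=residues)


def _charge_pair_kind(aa1: str, aa2: str) -> str | None:
    c1 = "-" if aa1 in ACIDIC else "+" if aa1 in BASIC else None
    c2 = "-" if aa2 in ACIDIC else "+" if aa2 in BASIC else None
    if c1 is None or c2 is None:
        return None
    return "like" if c1 == c2 else "opposite"


def electro_delta(seq: ProteinSequence, mutation: Mutation) -> float:
    """Intra-helical charge-pair change at (i, i+/-3) and (i, i+/-4).

    +1 per like-charge pair created, -1 per like-charge pair removed,
    -1 per opposite-charge pair created, +1 per opposite-charge pair removed.
    E.g. C54E next to E51 creates a like-charge (i, i+3) pair (+1,
    helix-destabilizing); C54R creates an opposite-charge pair (-1).
    """
    delta = 0.0
    for offset in (-4, -3, 3, 4):
        partner_pos = mutation.position + offset
        if not 1 <= partner_pos <= len(seq):
            continue
        partner = seq.residue(partner_pos)
        old = _charge_pair_kind(mutation.from_aa, partner)
        new = _charge_pair_kind(mutation.to_aa, partner)
        if old != new:
            if old == "like":
                delta -= 1.0
            elif old == "opposite":
                delta += 1.0
            if new == "like":
                delta += 1.0
            elif new == "opposite":
                delta -= 1.0
    return delta


def predict_mutation_effect(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    region: CoilRegion,
    template: CoiledCoilTemplate,
    mutation: Mutation,
    both_chains: bool = False,
    half_width: int = DEFAULT_HALF_WIDTH,
    cutoff: float = DEFAULT_CUTOFF,
) -> MutationEffect:
    """Qualitative effect of a substitution on dimer formation.

    The mutation is applied to chain A, or to both chains when
    ``both_chains`` is set (the natural choice for homodimers).  Known LSU1
    behavior reproduced by this rule: C54A neutral, C54E destabilizing
    (E51/E54 repulsion), C54R stabilizing (E51/R54 attraction), L60A
    destabilizing (zipper leucine lost), with a weaker zipper loss when only
    one chain of a heterodimer carries L60A.
    """
    wt_best = scan_register_shifts(
        seq_a, seq_b, region, template, half_width, cutoff
    ).best_score()
    mut_a = apply_mutation(seq_a, mutation)
    mut_b = apply_mutation(seq_b, mutation) if both_chains else seq_b
    mut_best = scan_register_shifts(
        mut_a, mut_b, region, template, half_width, cutoff
    ).best_score()
    zipper_d = mut_best - wt_best
    electro_d = electro_delta(seq_a, mutation) * (2.0 if both_chains else 1.0)

    if zipper_d < 0:
        verdict = "destabilizing"
    elif zipper_d > 0:
        verdict = "stabilizing"
    elif electro_d > 0:
        verdict = "destabilizing"
    elif electro_d < 0:
        verdict = "stabilizing"
    else:
        verdict = "neutral"
    context = "homodimer" if seq_a.id == seq_b.id else "heterodimer"
    return MutationEffect(
        verdict=verdict, zipper_delta=zipper_d, electro_delta=electro_d, context=context
    )


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------


def _write_pdb(
    template: CoiledCoilTemplate,
    chain_a: ChainPlacement,
    chain_b: ChainPlacement,
    path: str | Path,
) -> None:
    n_atoms = (len(chain_a) + len(chain_b)) * len(ATOM_NAMES)
    array = struc.AtomArray(n_atoms)
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    idx = 0
    for helix, chain_id, placement in ((0, "A", chain_a), (1, "B", chain_b)):
        for slot, pos, aa in zip(
            placement.slots, placement.res_positions, placement.residues
        ):
            res_name = seq3(aa).upper()
            for a, atom_name in enumerate(ATOM_NAMES):
                array.chain_id[idx] = chain_id
                array.res_id[idx] = int(pos)
                array.res_name[idx] = res_name
                array.atom_name[idx] = atom_name
                array.element[idx] = elements[atom_name]
                array.coord[idx] = template.coords[helix, slot, a, :]
                idx += 1
    pdb_file = PDBFile()
    pdb_file.set_structure(array)
    try:
        pdb_file.write(str(path))
    except OSError as exc:
        raise InputError(f"cannot write PDB file {path}: {exc}") from exc


def write_model_pdb(model: DimerModel, path: str | Path) -> None:
    """Write a threaded dimer as a two-chain PDB (chains A/B).

    Residue numbers are the original 1-based sequence positions, so mutated
    or truncated models stay aligned with the full-length numbering.
    """
    if len(model.chain_a) == 0 or len(model.chain_b) == 0:
        raise ValidationError("cannot write an empty dimer model")
    _write_pdb(model.template, model.chain_a, model.chain_b, path)
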