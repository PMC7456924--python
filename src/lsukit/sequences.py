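"""Protein sequences, coiled-coil regions, and leucine landmark bookkeeping.

Residue numbering is 1-based from the initiator methionine throughout, so a
"L60" label always means ``seq.residue(60) == "L"``.  Coil regions are
inclusive 1-based ranges; the default modeled span for LSU-family proteins is
residues 7-65, of which 9-39 is the segment predicted to be in a coiled-coil
conformation in every family member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import InputError, ValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

HEPTAD_LETTERS = "abcdefg"

#: Positions forming the hydrophobic seam of a coiled coil.
CORE_LETTERS = frozenset("ad")


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence, numbered 1-based."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r}: empty sequence")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise ValidationError(
                    f"sequence {self.id!r}: invalid residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """One-letter code at a 1-based position."""
        if not 1 <= position <= len(self):
            raise ValidationError(
                f"sequence {self.id!r}: position {position} outside 1..{len(self)}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class CoilRegion:
    """Inclusive 1-based span of the modeled coiled-coil segment."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start < self.end:
            raise ValidationError(f"invalid coil region [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def validate_for(self, seq: ProteinSequence) -> None:
        if self.end > len(seq):
            raise ValidationError(
                f"coil region [{self.start}, {self.end}] exceeds length of "
                f"{seq.id!r} ({len(seq)} residues)"
            )


#: Modeled span for LSU dimer models (Methods convention).
DEFAULT_COIL_REGION = CoilRegion(7, 65)
#: Span predicted coiled-coil in all four LSU proteins.
ALWAYS_COILED_REGION = CoilRegion(9, 39)


@dataclass(frozen=True)
class LeucineProfile:
    """The set of 1-based positions occupied by leucine in one sequence."""

    positions: frozenset[int]

    def __len__(self) -> int:
        return len(self.positions)


def parse_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`.

    Record ids are the header token up to the first whitespace; order is
    preserved.  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except OSError as exc:  # pragma: no cover - unreadable file
        raise InputError(f"cannot read FASTA file {path}: {exc}") from exc
    return [ProteinSequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences as plain uncompressed FASTA."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            for seq in seqs:
                fh.write(f">{seq.id}\n{seq.residues}\n")
    except OSError as exc:
        raise InputError(f"cannot write FASTA file {path}: {exc}") from exc


def packaged_lsu_fasta() -> Path:
    """Path of the synthetic LSU-like FASTA fixture shipped with the package."""
    return Path(__file__).parent / "data" / "lsu_synthetic.fasta"


def leucine_profile(seq: ProteinSequence) -> LeucineProfile:
    """All 1-based positions of 'L' in the sequence."""
    return LeucineProfile(
        frozenset(i for i, aa in enumerate(seq.residues, start=1) if aa == "L")
    )


def conserved_positions(profiles: Sequence[LeucineProfile]) -> frozenset[int]:
    """Intersection of leucine positions over one or more profiles.

    Commutative and idempotent in the profile list; for the four printed
    LSU leucine profiles the intersection is the seven family-conserved
    leucines {18, 29, 53, 57, 60, 65, 78}.
    """
    if not profiles:
        raise ValidationError("conserved_positions requires at least one profile")
    out = set(profiles[0].positions)
    for prof in profiles[1:]:
        out &= prof.positions
    return frozenset(out)


@dataclass(frozen=True)
class HeptadAssignment:
    """Heptad letters (a-g) assigned to each residue of a coil region."""

    region: CoilRegion
    phase: int
    letters: Mapping[int, str] = field(repr=False)

    def letter(self, position: int) -> str:
        return self.letters[position]

    def core_positions(self) -> frozenset[int]:
        """Positions at the hydrophobic a/d seam."""
        return frozenset(p for p, c in self.letters.items() if c in CORE_LETTERS)


def assign_heptad(
    seq: ProteinSequence, region: CoilRegion, phase: int
) -> HeptadAssignment:
    """Assign cycling heptad letters over ``region``.

    ``phase`` indexes the letter given to ``region.start`` (0 = 'a').
    """
    if not 0 <= phase <= 6:
        raise ValidationError(f"heptad phase must be in 0..6, got {phase}")
    region.validate_for(seq)
    letters = {
        pos: HEPTAD_LETTERS[(phase + k) % 7]
        for k, pos in enumerate(region.positions())
    }
    return HeptadAssignment(region=region, phase=phase, letters=letters)


def auto_phase(seq: ProteinSequence, region: CoilRegion) -> int:
    """Phase placing the most leucines at core (a/d) positions.

    Brute-forces the seven possible phases; ties break to the lowest phase
    index so the choice is deterministic.
    """
    region.validate_for(seq)
    leus = leucine_profile(seq).positions & frozenset(region.positions())
    best_phase, best_count = 0, -1
    for phase in range(7):
        assignment = assign_heptad(seq, region, phase)
        count = len(leus & assignment.core_positions())
        if count > best_count:
            best_phase, best_count = phase, count
    return best_phase
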