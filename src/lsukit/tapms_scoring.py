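"""Semi-quantitative scoring of TAP-MS protein-group intensity tables.

The statistics follow the standard intensity-comparison recipe for tandem
affinity purification screens:

* **abundance** of a protein in a dataset = mean MaxQuant intensity over the
  probe replicates divided by the protein's molecular weight (kDa);
* **relative specificity** = log10( median probe intensity / median control
  intensity ), with the control background arbitrarily set to 1 for proteins
  never detected in the control;
* proteins with relative specificity strictly greater than 1 are **candidate
  partners** of the bait in that dataset.

A dataset is one (bait line, growth condition) combination; the full design
is four TAP-tagged baits (LSU1-4) x four conditions (4 or 10 days, sulfur
sufficient or deficient) = 16 datasets, plus a tag-only control line per
condition.  Undetected replicates contribute observed zeros to the median;
only the all-undetected control case invokes the background = 1 rule, and a
protein undetected in every probe replicate gets a NaN sentinel and is never
a candidate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ValidationError

logger = logging.getLogger(__name__)

CONTROL_BAIT = "control-TAP"
BAITS = ("LSU1-TAP", "LSU2-TAP", "LSU3-TAP", "LSU4-TAP")
CONDITIONS = ("4d_nS", "4d-S", "10d_nS", "10d-S")
LSU_NAMES = ("LSU1", "LSU2", "LSU3", "LSU4")
#: MaxQuant contaminant / reversed-decoy id prefixes.
CONTAMINANT_PREFIXES = ("CON__", "REV__")
DEFAULT_THRESHOLD = 1.0  # log10 units; strict '>' comparison

#: Sentinel relative specificity for proteins undetected in every probe
#: replicate (never candidates).
NOT_DETECTED = float("nan")


@dataclass(frozen=True)
class SampleDesign:
    """Maps intensity columns to (bait, condition, replicate)."""

    frame: pd.DataFrame  # columns: sample, bait, condition, replicate

    def __post_init__(self) -> None:
        required = {"sample", "bait", "condition", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ConfigurationError(f"design table missing columns: {sorted(missing)}")
        dup = self.frame["sample"][self.frame["sample"].duplicated()]
        if not dup.empty:
            raise ConfigurationError(
                f"duplicated sample mapping in design: {sorted(dup.unique())}"
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleDesign":
        path = Path(path)
        if not path.exists():
            raise InputError(f"design table not found: {path}")
        return cls(pd.read_csv(path, sep="\t", dtype={"sample": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"])

    def baits(self) -> list[str]:
        return [b for b in self.frame["bait"].unique() if b != CONTROL_BAIT]

    def conditions(self) -> list[str]:
        return list(self.frame["condition"].unique())

    def probe_samples(self, bait: str, condition: str) -> list[str]:
        sel = (self.frame["bait"] == bait) & (self.frame["condition"] == condition)
        return list(self.frame.loc[sel, "sample"])

    def control_samples(self, condition: str) -> list[str]:
        return self.probe_samples(CONTROL_BAIT, condition)


@dataclass(frozen=True)
class IntensityTable:
    """Protein-group intensities by sample, plus molecular weight (kDa)."""

    frame: pd.DataFrame  # columns: group_id, mw_kda, <sample columns>

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("group_id", "mw_kda")]

    @property
    def group_ids(self) -> list[str]:
        return list(self.frame["group_id"])

    def intensities(self, group_id: str, samples: Sequence[str]) -> np.ndarray:
        row = self.frame.loc[self.frame["group_id"] == group_id]
        if row.empty:
            raise ValidationError(f"unknown protein group {group_id!r}")
        return row[list(samples)].to_numpy(dtype=float).ravel()

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def is_ambiguous_group(group_id: str) -> bool:
    """Protein groups whose members cannot be resolved by MS carry a '/'."""
    return "/" in group_id


def read_intensity_table(
    path: str | Path,
    design_path: str | Path,
    contaminant_prefixes: Iterable[str] = CONTAMINANT_PREFIXES,
) -> tuple[IntensityTable, SampleDesign]:
    """Read a proteinGroups-style TSV plus its sample-design TSV.

    Contaminant/decoy rows (default MaxQuant CON__/REV__ prefixes) are
    dropped with a logged count.  Every intensity column must be mapped in
    the design and vice versa.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"intensity table not found: {path}")
    design = SampleDesign.read_tsv(design_path)
    frame = pd.read_csv(path, sep="\t", dtype={"group_id": str})
    for col in ("group_id", "mw_kda"):
        if col not in frame.columns:
            raise ValidationError(f"intensity table missing column {col!r}")
    mw = pd.to_numeric(frame["mw_kda"], errors="coerce")
    if mw.isna().any() or (mw <= 0).any():
        bad = frame.loc[mw.isna() | (mw <= 0), "group_id"].tolist()
        raise ValidationError(f"non-numeric or non-positive molecular weight for {bad}")
    frame["mw_kda"] = mw

    sample_cols = [c for c in frame.columns if c not in ("group_id", "mw_kda")]
    unmapped = set(sample_cols) - set(design.samples)
    if unmapped:
        raise ConfigurationError(
            f"intensity columns not mapped in design: {sorted(unmapped)}"
        )
    missing = set(design.samples) - set(sample_cols)
    if missing:
        raise ConfigurationError(
            f"design samples absent from intensity table: {sorted(missing)}"
        )
    for col in sample_cols:
        frame[col] = pd.to_numeric(frame[col], errors="coerce").fillna(0.0)
        if (frame[col] < 0).any():
            raise ValidationError(f"negative intensity in column {col!r}")

    prefixes = tuple(contaminant_prefixes)
    mask = frame["group_id"].str.startswith(prefixes) if prefixes else pd.Series(
        False, index=frame.index
    )
    if mask.any():
        logger.info("dropped %d contaminant/decoy rows", int(mask.sum()))
        frame = frame.loc[~mask].reset_index(drop=True)
    return IntensityTable(frame), design


def abundance(mean_intensity: float, mw_kda: float) -> float:
    """Mean probe intensity divided by molecular weight (kDa)."""
    if mw_kda <= 0:
        raise ValidationError(f"molecular weight must be positive, got {mw_kda}")
    return mean_intensity / mw_kda


def relative_specificity(
    probe_intensities: Sequence[float], control_intensities: Sequence[float]
) -> float:
    """log10( median(probe) / median(control) ) with background handling.

    The control median is replaced by 1 when the protein is undetected in all
    control replicates (the arbitrary background level).  Returns the
    :data:`NOT_DETECTED` NaN sentinel when all probe replicates are zero, and
    -inf when the probe median is zero despite some detection.
    """
    probe = np.asarray(probe_intensities, dtype=float)
    if probe.size == 0:
        raise ValidationError("relative_specificity requires >= 1 probe replicate")
    control = np.asarray(control_intensities, dtype=float)
    if not np.any(probe > 0):
        return NOT_DETECTED
    median_probe = float(np.median(probe))
    median_control = float(np.median(control)) if control.size else 0.0
    if not np.any(control > 0):
        median_control = 1.0
    elif median_control == 0.0:
        median_control = 1.0
    if median_probe == 0.0:
        return -math.inf
    return math.log10(median_probe / median_control)


def _bait_matches_group(bait: str, group_id: str, lsu_names: Sequence[str]) -> bool:
    short = bait.replace("-TAP", "")
    return short in lsu_names and short in group_id.split("/")


def call_candidates(
    table: IntensityTable,
    design: SampleDesign,
    threshold: float = DEFAULT_THRESHOLD,
    lsu_names: Sequence[str] = LSU_NAMES,
) -> pd.DataFrame:
    """One specificity record per (protein group, bait, condition).

    Columns: group_id, bait, condition, abundance, relative_specificity,
    candidate, is_bait, ambiguous.  Candidate = relative specificity strictly
    above ``threshold`` and detection in at least one probe replicate.  A
    bait's own protein group (including ambiguous "LSU2/LSU4"-style groups)
    is scored like any other but flagged ``is_bait``.
    """
    records = []
    frame = table.frame
    for bait in design.baits():
        for condition in design.conditions():
            probe_cols = design.probe_samples(bait, condition)
            control_cols = design.control_samples(condition)
            if not probe_cols:
                continue
            probe = frame[probe_cols].to_numpy(dtype=float)
            control = (
                frame[control_cols].to_numpy(dtype=float)
                if control_cols
                else np.zeros((len(frame), 0))
            )
            for i, group_id in enumerate(frame["group_id"]):
                rs = relative_specificity(probe[i], control[i])
                records.append(
                    {
                        "group_id": group_id,
                        "bait": bait,
                        "condition": condition,
                        "abundance": abundance(
                            float(probe[i].mean()), float(frame["mw_kda"].iloc[i])
                        ),
                        "relative_specificity": rs,
                        "candidate": bool(np.isfinite(rs) and rs > threshold),
                        "is_bait": _bait_matches_group(bait, group_id, lsu_names),
                        "ambiguous": is_ambiguous_group(group_id),
                    }
                )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class IncidenceSummary:
    """Candidate incidence per protein group across bait x condition datasets."""

    frame: pd.DataFrame  # group_id, incidence, per-bait columns
    n_datasets: int

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def incidence(records: pd.DataFrame) -> IncidenceSummary:
    """Count, per protein group, the datasets in which it is a candidate.

    With the full four-bait, four-condition design the maximum incidence is
    16.  Bait self-detections are excluded from partner incidence (they are
    reported by :func:`bait_detection_report` instead).
    """
    datasets = records[["bait", "condition"]].drop_duplicates()
    n_datasets = len(datasets)
    partners = records.loc[~records["is_bait"]]
    counts = (
        partners.groupby("group_id")["candidate"].sum().astype(int).rename("incidence")
    )
    per_bait = (
        partners.groupby(["group_id", "bait"])["candidate"]
        .sum()
        .astype(int)
        .unstack(fill_value=0)
    )
    per_bait.columns = [f"n_{b}" for b in per_bait.columns]
    frame = pd.concat([counts, per_bait], axis=1).reset_index()
    frame = frame.sort_values(
        ["incidence", "group_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return IncidenceSummary(frame=frame, n_datasets=n_datasets)


def bait_detection_report(
    table: IntensityTable,
    design: SampleDesign,
    lsu_group_ids: Sequence[str] | None = None,
    lsu_names: Sequence[str] = LSU_NAMES,
) -> pd.DataFrame:
    """Which LSU proteins are detected in which bait line and condition.

    Ambiguous groups (e.g. "LSU2/LSU4", where MS cannot distinguish the two
    proteins) are listed once per member LSU with ``ambiguous=True``.
    Detection = nonzero intensity in any probe replicate of the dataset.
    """
    if lsu_group_ids is None:
        lsu_group_ids = [
            g
            for g in table.group_ids
            if any(part in lsu_names for part in g.split("/"))
        ]
    rows = []
    for bait in design.baits():
        for condition in design.conditions():
            probe_cols = design.probe_samples(bait, condition)
            if not probe_cols:
                continue
            for group_id in lsu_group_ids:
                values = table.intensities(group_id, probe_cols)
                detected = bool(np.any(values > 0))
                for lsu in group_id.split("/"):
                    if lsu not in lsu_names:
                        continue
                    rows.append(
                        {
                            "bait_line": bait,
                            "condition": condition,
                            "lsu": lsu,
                            "group_id": group_id,
                            "detected": detected,
                            "ambiguous": is_ambiguous_group(group_id),
                        }
                    )
    return pd.DataFrame.from_records(
        rows, columns=["bait_line", "condition", "lsu", "group_id", "detected", "ambiguous"]
    )
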