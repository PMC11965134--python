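"""ROI statistics: per-subject parameter means and two-reader merging.

Subjects contribute one region of interest per reader; map values are
averaged over the ROI (excluding failed-fit voxels, which are NaN in the
maps) and, when two readers delineated the lesion, the two means are
averaged again to give the subject's record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import ParameterMaps
from .model import DegenerateInputError, ValidationError

__all__ = [
    "STAT_PARAMS",
    "ROIMask",
    "SubjectRecord",
    "CohortTable",
    "roi_mean",
    "combine_readers",
    "extract_subject",
]

#: The nine quantities carried into the statistical stage.
STAT_PARAMS: tuple[str, ...] = (
    "D_r", "D_h", "D_f", "f_r", "f_h", "f_ui", "f_f", "alpha_h", "ADC",
)

GRADES = ("low", "high")


@dataclass(frozen=True)
class ROIMask:
    """A reader's binary region of interest over one subject's maps."""

    mask: np.ndarray
    subject_id: str
    reader: str = "reader1"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValidationError(f"ROI for {self.subject_id} has no voxels")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's ROI-mean parameters with grade label."""

    subject_id: str
    grade: str
    values: dict[str, float]
    n_voxels: int = 1

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValidationError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if self.n_voxels < 1:
            raise ValidationError("n_voxels must be >= 1")
        missing = [p for p in STAT_PARAMS if p not in self.values]
        if missing:
            raise ValidationError(f"record missing parameters: {missing}")
        for name in ("f_r", "f_h", "f_ui", "f_f"):
            v = self.values[name]
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("D_r", "D_h", "D_f", "ADC"):
            if self.values[name] < 0:
                raise ValidationError(f"{name} must be >= 0")

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class CohortTable:
    """Per-subject records plus provenance (real data or synthetic seed)."""

    records: list[SubjectRecord]
    provenance: str = "real"
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("subject ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def grades_present(self) -> set[str]:
        return {r.grade for r in self.records}

    def group_values(self, param: str) -> tuple[np.ndarray, np.ndarray]:
        """(low-grade values, high-grade values) for one parameter."""
        low = np.array([r[param] for r in self.records if r.grade == "low"])
        high = np.array([r[param] for r in self.records if r.grade == "high"])
        return low, high

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"subject_id": r.subject_id, "grade": r.grade,
             **{p: r[p] for p in STAT_PARAMS}, "n_voxels": r.n_voxels}
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, provenance: str = "real", seed: int | None = None
    ) -> "CohortTable":
        records = [
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                grade=str(row["grade"]),
                values={p: float(row[p]) for p in STAT_PARAMS},
                n_voxels=int(row.get("n_voxels", 1)),
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, provenance=provenance, seed=seed)


def roi_mean(map3d: np.ndarray, mask: "ROIMask | np.ndarray") -> tuple[float, int]:
    """Arithmetic mean of a map over masked, non-NaN voxels.

    Returns (mean, n_voxels_used). NaN voxels inside the mask are failed
    fits and are excluded rather than imputed.
    """
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    grid = np.asarray(map3d, dtype=float)
    if grid.shape != m.shape:
        raise ValidationError(f"map shape {grid.shape} != mask shape {m.shape}")
    vals = grid[m]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DegenerateInputError("no valid (non-NaN) voxels under the mask")
    return float(vals.mean()), int(vals.size)


def combine_readers(record_a: SubjectRecord, record_b: SubjectRecord) -> SubjectRecord:
    """Average two readers' measurements of the same subject, per parameter."""
    if record_a.subject_id != record_b.subject_id:
        raise ValidationError(
            f"subject ids differ: {record_a.subject_id!r} vs {record_b.subject_id!r}"
        )
    if record_a.grade != record_b.grade:
        raise ValidationError("grade labels differ between readers")
    merged = {p: 0.5 * (record_a[p] + record_b[p]) for p in STAT_PARAMS}
    n = int(round(0.5 * (record_a.n_voxels + record_b.n_voxels)))
    return SubjectRecord(
        subject_id=record_a.subject_id,
        grade=record_a.grade,
        values=merged,
        n_voxels=max(n, 1),
    )


def extract_subject(
    maps: ParameterMaps,
    masks: list[ROIMask],
    grade: str,
) -> SubjectRecord:
    """Build one subject's record from parameter maps and 1-2 reader ROIs."""
    if not 1 <= len(masks) <= 2:
        raise ValidationError(f"expected 1 or 2 masks, got {len(masks)}")
    per_reader = []
    for roi in masks:
        vals, n = {}, 0
        for p in STAT_PARAMS:
            vals[p], n = roi_mean(maps[p], roi)
        per_reader.append(
            SubjectRecord(subject_id=roi.subject_id, grade=grade, values=vals, n_voxels=n)
        )
    if len(per_reader) == 1:
        return per_reader[0]
    return combine_readers(per_reader[0], per_reader[1])
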