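"""Harmonize raw epoch records into normalized 720-point daytime segments.

The rules: triaxial counts are collapsed with the vector-magnitude formula;
nighttime epochs (21:00-09:00) are discarded because subjects remove the
device at bedtime; days with a daytime missing run of more than 30 consecutive
minutes are excluded; surviving short gaps are linearly interpolated; values
are standardized with dataset-level mean/SD computed from daytime values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MINUTES_PER_DAY, EpochRecord

__all__ = [
    "DAY_START_MIN",
    "DAY_END_MIN",
    "SEGMENT_LENGTH",
    "NormalizationStats",
    "DaySegment",
    "Exclusion",
    "vector_magnitude",
    "longest_missing_run",
    "compute_normalization_stats",
    "extract_day_segments",
    "preprocess_records",
    "segments_to_matrix",
]

DAY_START_MIN = 9 * 60  # 09:00 inclusive
DAY_END_MIN = 21 * 60  # 21:00 exclusive
SEGMENT_LENGTH = DAY_END_MIN - DAY_START_MIN  # 720


@dataclass(frozen=True)
class NormalizationStats:
    """Dataset-level standardization parameters (sample SD, ddof=1)."""

    mean: float
    sd: float
    scope: str = "per-dataset"

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.sd

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * self.sd + self.mean


@dataclass
class DaySegment:
    """720 normalized daytime (09:00-21:00) values of one retained day."""

    subject_id: str
    date: str
    values: np.ndarray
    source_stats: NormalizationStats

    def __post_init__(self) -> None:
        if self.values.shape != (SEGMENT_LENGTH,):
            raise ValueError(f"segment must have length {SEGMENT_LENGTH}")
        if not np.isfinite(self.values).all():
            raise ValueError("segment values must be finite")


@dataclass(frozen=True)
class Exclusion:
    subject_id: str
    date: str
    reason: str
    run_length: int


def vector_magnitude(
    triaxial_counts: np.ndarray, missing_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse triaxial counts to sqrt(x^2 + y^2 + z^2) per epoch.

    Returns (magnitude, missing_mask); an epoch is missing if any axis is.
    """
    triaxial_counts = np.asarray(triaxial_counts, dtype=float)
    if triaxial_counts.ndim != 2 or triaxial_counts.shape[1] != 3:
        raise ValueError("triaxial counts must be n x 3")
    if missing_mask is None:
        missing_mask = np.isnan(triaxial_counts)
    if missing_mask.shape != triaxial_counts.shape:
        raise ValueError("mask must align with counts")
    any_missing = missing_mask.any(axis=1)
    mag = np.sqrt(np.nansum(triaxial_counts**2, axis=1))
    mag[any_missing] = np.nan
    return mag, any_missing


def longest_missing_run(mask: np.ndarray) -> int:
    """Length of the longest contiguous True run (0 if none)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    if edges.size == 0:
        return 0
    starts, ends = edges[0::2], edges[1::2]
    return int((ends - starts).max())


def _uniaxial(record: EpochRecord) -> tuple[np.ndarray, np.ndarray]:
    if record.triaxial:
        return vector_magnitude(record.counts, record.missing_mask)
    return record.counts, record.missing_mask


def compute_normalization_stats(
    records: list[EpochRecord], daytime_only: bool = True
) -> NormalizationStats:
    """Pooled mean/SD over non-missing (daytime, by default) epoch values.

    Daytime-only is the default because nighttime epochs are discarded before
    any model sees the data; statistics over removed values would shift the
    standardized scale for no benefit.
    """
    chunks = []
    for rec in records:
        counts, mask = _uniaxial(rec)
        if daytime_only:
            counts = counts[DAY_START_MIN:DAY_END_MIN]
            mask = mask[DAY_START_MIN:DAY_END_MIN]
        chunks.append(counts[~mask])
    values = np.concatenate(chunks) if chunks else np.empty(0)
    if values.size == 0:
        raise ValueError("no non-missing values to compute statistics from")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("degenerate input: SD is zero")
    return NormalizationStats(mean=mean, sd=sd)


def extract_day_segments(
    record: EpochRecord,
    stats: NormalizationStats,
    max_missing_run: int = 30,
) -> DaySegment | Exclusion:
    """Keep minutes [09:00, 21:00), exclude the day on a >30-min missing run.

    Night content never influences the decision.  Gaps of at most
    ``max_missing_run`` minutes are linearly interpolated (edge gaps extended
    with the nearest observed value); the result is standardized with
    ``stats``.  Exclusion is a normal outcome, returned with the reason.
    """
    counts, mask = _uniaxial(record)
    day = counts[DAY_START_MIN:DAY_END_MIN].astype(float)
    day_mask = mask[DAY_START_MIN:DAY_END_MIN]
    run = longest_missing_run(day_mask)
    if run > max_missing_run:
        return Exclusion(record.subject_id, record.date, "missing_run", run)
    if day_mask.all():
        return Exclusion(record.subject_id, record.date, "all_missing", run)
    if day_mask.any():
        idx = np.arange(SEGMENT_LENGTH)
        day[day_mask] = np.interp(idx[day_mask], idx[~day_mask], day[~day_mask])
    return DaySegment(
        subject_id=record.subject_id,
        date=record.date,
        values=stats.apply(day),
        source_stats=stats,
    )


def preprocess_records(
    records: list[EpochRecord],
    stats: NormalizationStats | None = None,
    max_missing_run: int = 30,
) -> tuple[list[DaySegment], pd.DataFrame]:
    """Run the full per-day pipeline; returns retained segments + exclusion log."""
    if stats is None:
        stats = compute_normalization_stats(records)
    segments: list[DaySegment] = []
    exclusions: list[Exclusion] = []
    for rec in records:
        out = extract_day_segments(rec, stats, max_missing_run=max_missing_run)
        if isinstance(out, DaySegment):
            segments.append(out)
        else:
            exclusions.append(out)
    log = pd.DataFrame(
        [(e.subject_id, e.date, e.reason, e.run_length) for e in exclusions],
        columns=["subject_id", "date", "reason", "run_length"],
    )
    return segments, log


def segments_to_matrix(segments: list[DaySegment]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack segments into (n_days x 720) with an aligned (subject, date) index."""
    if not segments:
        raise ValueError("no segments to stack")
    mat = np.stack([s.values for s in segments])
    index = pd.DataFrame(
        [(s.subject_id, s.date) for s in segments], columns=["subject_id", "date"]
    )
    return mat, index
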