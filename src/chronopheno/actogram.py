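"""Wheel-running activity records, light-schedule plans, and their file formats.

The canonical interchange format is a per-subject CSV with header
``subject_id,timestamp_iso,counts``: one row per acquisition bin (5 min by
default), counts stored as integer wheel revolutions *per bin* so that rebinning
is exactly conservative. A cohort manifest CSV maps ``subject_id`` to genotype
and dose; the experiment structure (LD/DD segments, treatment windows) lives in
a YAML phase plan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ActivityRecord",
    "Segment",
    "PhasePlan",
    "ZTime",
    "ActogramError",
    "GapError",
    "read_activity_csv",
    "write_activity_csv",
    "read_manifest_csv",
    "read_phase_plan",
    "rebin",
    "slice_phase",
    "slice_days",
    "hourly_counts",
]

GENOTYPES = ("APP-PS1", "nTg")
DOSES = (0.0, 10.0, 30.0)


class ActogramError(ValueError):
    """Invalid activity data or schedule."""


class GapError(ActogramError):
    """Non-equidistant timestamps: one or more acquisition bins are missing."""

    def __init__(self, missing: Sequence[datetime]):
        self.missing = list(missing)
        shown = ", ".join(t.isoformat() for t in self.missing[:5])
        more = "" if len(self.missing) <= 5 else f" (+{len(self.missing) - 5} more)"
        super().__init__(f"missing {len(self.missing)} bin(s): {shown}{more}")


@dataclass
class ActivityRecord:
    """One subject's binned wheel-revolution counts.

    counts[i] is the number of wheel revolutions in the bin starting at
    ``t0 + i*bin_minutes``. Counts are revolutions per bin; divide by
    ``bin_minutes`` for counts/min at presentation time.
    """

    subject_id: str
    t0: datetime
    bin_minutes: int
    counts: np.ndarray
    genotype: str | None = None
    dose_mg_kg: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ActogramError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0):
            raise ActogramError("negative counts are invalid")
        if (not float(self.bin_minutes).is_integer() or self.bin_minutes < 1
                or 60 % int(self.bin_minutes)):
            raise ActogramError(f"bin_minutes={self.bin_minutes} must divide 60")
        self.bin_minutes = int(self.bin_minutes)
        self.counts = self.counts.astype(np.int64)
        if self.genotype is not None and self.genotype not in GENOTYPES:
            raise ActogramError(f"unknown genotype {self.genotype!r}")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bins_per_day(self) -> int:
        return 24 * 60 // self.bin_minutes

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_minutes / 60.0

    @property
    def duration_days(self) -> float:
        return self.duration_hours / 24.0

    def bin_start_hours(self) -> np.ndarray:
        """Start time of each bin in hours since t0."""
        return np.arange(self.n_bins) * (self.bin_minutes / 60.0)

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.t0, periods=self.n_bins,
                             freq=pd.Timedelta(minutes=self.bin_minutes))


@dataclass(frozen=True)
class Segment:
    """One contiguous lighting/treatment segment, in whole days from record start."""

    label: str
    start_day: int
    end_day: int
    lighting: str  # "LD" or "DD"
    lights_on_hour: float | None = None
    lights_off_hour: float | None = None
    treatment: str = "none"  # none | vehicle | PF10 | PF30

    def __post_init__(self) -> None:
        if self.lighting not in ("LD", "DD"):
            raise ActogramError(f"lighting must be LD or DD, got {self.lighting!r}")
        if self.end_day <= self.start_day or self.start_day < 0:
            raise ActogramError(f"segment {self.label!r}: bad day range")
        if self.lighting == "LD":
            if self.lights_on_hour is None or self.lights_off_hour is None:
                raise ActogramError(f"LD segment {self.label!r} needs lights on/off hours")
        elif self.lights_on_hour is not None or self.lights_off_hour is not None:
            raise ActogramError(f"DD segment {self.label!r} must not carry lights on/off")
        if self.treatment not in ("none", "vehicle", "PF10", "PF30"):
            raise ActogramError(f"unknown treatment {self.treatment!r}")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day


@dataclass
class PhasePlan:
    """Ordered, contiguous, non-overlapping experiment segments."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise ActogramError("segment labels must be unique")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_day != a.end_day:
                raise ActogramError(
                    f"segments {a.label!r} and {b.label!r} are not contiguous")

    def __getitem__(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]

    @property
    def total_days(self) -> int:
        return self.segments[-1].end_day if self.segments else 0


@dataclass(frozen=True)
class ZTime:
    """A time of day in [0, 24) under a stated reference frame.

    ZT0 = lights-on under LD; CT is anchored to the subject's activity onset in
    DD, with onset at CT12 (nocturnal convention). ``clock`` is wall time.
    ``abs_hours`` optionally carries the absolute time (hours since record
    start) the value was derived from.
    """

    value: float
    reference: str = "ZT"  # ZT | CT | clock
    abs_hours: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.value < 24):
            raise ActogramError(f"time-of-day value {self.value} outside [0, 24)")
        if self.reference not in ("ZT", "CT", "clock"):
            raise ActogramError(f"unknown reference {self.reference!r}")


# ---------------------------------------------------------------------------
# file formats


def write_activity_csv(record: ActivityRecord, path: str | Path) -> None:
    """Write the canonical per-subject activity CSV."""
    df = pd.DataFrame({
        "subject_id": record.subject_id,
        "timestamp_iso": record.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
        "counts": record.counts,
    })
    df.to_csv(path, index=False)


def read_activity_csv(path: str | Path, schema: dict[str, str] | None = None,
                      zero_fill: bool = False) -> ActivityRecord:
    """Read and validate a canonical activity CSV.

    Parameters
    ----------
    schema
        Optional column mapping with keys ``subject_id``, ``timestamp``,
        ``counts`` naming the columns in the file; defaults to the canonical
        header ``subject_id,timestamp_iso,counts``.
    zero_fill
        If True, missing bins are filled with zero counts instead of raising
        :class:`GapError`. Off by default: silent imputation corrupts
        fragmentation statistics.
    """
    schema = schema or {}
    col_sub = schema.get("subject_id", "subject_id")
    col_ts = schema.get("timestamp", "timestamp_iso")
    col_ct = schema.get("counts", "counts")
    df = pd.read_csv(path)
    for col in (col_sub, col_ts, col_ct):
        if col not in df.columns:
            raise ActogramError(f"{path}: missing column {col!r}")
    try:
        ts = pd.to_datetime(df[col_ts], format="ISO8601")
    except (ValueError, TypeError) as exc:
        bad = pd.to_datetime(df[col_ts], format="ISO8601", errors="coerce")
        line = int(np.argmax(bad.isna().to_numpy())) + 2  # 1-based + header
        raise ActogramError(f"{path}: malformed timestamp at line {line}") from exc
    counts = pd.to_numeric(df[col_ct], errors="coerce")
    if counts.isna().any():
        line = int(np.argmax(counts.isna().to_numpy())) + 2
        raise ActogramError(f"{path}: malformed counts at line {line}")
    if (counts < 0).any():
        line = int(np.argmax((counts < 0).to_numpy())) + 2
        raise ActogramError(f"{path}: negative counts at line {line}")

    diffs = ts.diff().dropna()
    step = diffs.min()
    if len(ts) < 2:
        raise ActogramError(f"{path}: need at least 2 rows to infer bin width")
    bin_minutes = step.total_seconds() / 60.0
    if not bin_minutes.is_integer() or bin_minutes <= 0:
        raise ActogramError(f"{path}: non-integer bin width {bin_minutes} min")
    full = pd.date_range(ts.iloc[0], ts.iloc[-1], freq=step)
    if len(full) != len(ts) or not (pd.DatetimeIndex(ts) == full).all():
        missing = full.difference(pd.DatetimeIndex(ts))
        if not zero_fill or len(missing) == 0:
            raise GapError(list(missing.to_pydatetime()))
        series = pd.Series(counts.to_numpy(), index=pd.DatetimeIndex(ts))
        series = series.reindex(full, fill_value=0)
        counts = pd.Series(series.to_numpy())
        ts = pd.Series(full)
    return ActivityRecord(
        subject_id=str(df[col_sub].iloc[0]),
        t0=ts.iloc[0].to_pydatetime(),
        bin_minutes=int(bin_minutes),
        counts=counts.to_numpy(dtype=np.int64),
    )


def read_manifest_csv(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest (subject_id, genotype, dose_mg_kg [, group])."""
    df = pd.read_csv(path)
    for col in ("subject_id", "genotype", "dose_mg_kg"):
        if col not in df.columns:
            raise ActogramError(f"{path}: manifest missing column {col!r}")
    bad = set(df["genotype"]) - set(GENOTYPES)
    if bad:
        raise ActogramError(f"{path}: unknown genotypes {sorted(bad)}")
    return df


def read_phase_plan(path: str | Path) -> PhasePlan:
    """Read a YAML phase plan: a list of segment mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("segments", raw)
    segments = [Segment(**{str(k): v for k, v in item.items()}) for item in raw]
    return PhasePlan(segments=segments)


def write_phase_plan(plan: PhasePlan, path: str | Path) -> None:
    items = []
    for s in plan.segments:
        d = {"label": s.label, "start_day": s.start_day, "end_day": s.end_day,
             "lighting": s.lighting, "treatment": s.treatment}
        if s.lighting == "LD":
            d["lights_on_hour"] = s.lights_on_hour
            d["lights_off_hour"] = s.lights_off_hour
        items.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump({"segments": items}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# transformations


def rebin(record: ActivityRecord, new_bin_minutes: int) -> ActivityRecord:
    """Sum counts into wider bins; total counts are conserved.

    ``new_bin_minutes`` must be a multiple of the record's bin width. A trailing
    partial bin is dropped (and reported via a warning) so every output bin
    covers exactly ``new_bin_minutes``.
    """
    if new_bin_minutes % record.bin_minutes:
        raise ActogramError(
            f"new bin width {new_bin_minutes} is not a multiple of {record.bin_minutes}")
    factor = new_bin_minutes // record.bin_minutes
    if factor == 1:
        return replace(record, counts=record.counts.copy())
    n_full = record.n_bins // factor
    dropped = record.n_bins - n_full * factor
    if dropped:
        warnings.warn(
            f"rebin: dropped trailing partial bin of {dropped} x "
            f"{record.bin_minutes} min ({int(record.counts[n_full * factor:].sum())} counts)",
            stacklevel=2)
    counts = record.counts[: n_full * factor].reshape(n_full, factor).sum(axis=1)
    return replace(record, bin_minutes=int(new_bin_minutes), counts=counts)


def slice_days(record: ActivityRecord, start_day: int, end_day: int) -> ActivityRecord:
    """Sub-record spanning [start_day, end_day) whole days from t0."""
    bpd = record.bins_per_day
    lo, hi = start_day * bpd, end_day * bpd
    if hi > record.n_bins:
        raise ActogramError(
            f"days [{start_day}, {end_day}) extend past record end "
            f"({record.duration_days:.2f} days available)")
    return replace(record,
                   t0=record.t0 + timedelta(days=start_day),
                   counts=record.counts[lo:hi].copy())


def slice_phase(record: ActivityRecord, plan: PhasePlan, label: str) -> ActivityRecord:
    """Sub-record for a named phase-plan segment, aligned to day boundaries of t0."""
    seg = plan[label]
    return slice_days(record, seg.start_day, seg.end_day)


def hourly_counts(record: ActivityRecord) -> np.ndarray:
    """Counts per hour (trailing partial hour dropped)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rebin(record, 60).counts.astype(float)
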