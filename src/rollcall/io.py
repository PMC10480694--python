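"""Reading, validating and writing the tabular formats used by the pipeline.

Raw traces arrive as CSV with a time column (seconds since deployment
start) and three acceleration columns in units of g: x = surge
(anterior-posterior), y = sway (lateral), z = heave (dorso-ventral).
Column names are remappable via :class:`TraceSchema` for loggers whose
firmware writes different headers, and inputs recorded in m/s^2 can be
converted at load (1 g = 9.807 m/s^2).

Per-dive and per-bird summary tables use fixed, documented column orders
so that downstream stages and external tools can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TraceSchema",
    "AccelTrace",
    "BirdMetadata",
    "LoadReport",
    "QCReport",
    "SchemaError",
    "TraceError",
    "G_PER_MS2",
    "DIVE_TABLE_COLUMNS",
    "BIRD_TABLE_COLUMNS",
    "read_accel_csv",
    "write_dive_table",
    "read_dive_table",
    "write_bird_table",
    "validate_trace",
]

#: 1 g in m/s^2, used when converting logger output recorded in SI units.
G_PER_MS2 = 9.807

#: Logger full-scale range in g; samples at or beyond this are clipped.
FULL_SCALE_G = 16.0

DIVE_TABLE_COLUMNS = [
    "bird_id",
    "date",
    "t_start_s",
    "t_end_s",
    "roll_mean_deg",
    "direction",
    "n_roll_samples",
]

BIRD_TABLE_COLUMNS = ["bird_id", "n_dives", "n_left", "n_right", "LI", "class"]


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


class TraceError(ValueError):
    """The trace violates a structural invariant (ordering, emptiness)."""


@dataclass(frozen=True)
class TraceSchema:
    """Column mapping and unit convention for a raw trace CSV."""

    time: str = "time"
    x: str = "ax"
    y: str = "ay"
    z: str = "az"
    #: "g" (default) or "ms2"; the latter is divided by 9.807 at load.
    units: str = "g"


@dataclass(frozen=True)
class BirdMetadata:
    bird_id: str
    colony: str = ""
    sex: str = "unknown"  # {female, male, unknown}
    deployment_start: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.sex not in {"female", "male", "unknown"}:
            raise ValueError(f"sex must be female/male/unknown, got {self.sex!r}")


@dataclass
class LoadReport:
    n_rows: int
    n_kept: int
    drop_count: int  # rows dropped for non-finite acceleration


@dataclass
class QCReport:
    duration_s: float
    effective_rate_hz: float
    gap_count: int  # inter-sample gaps > 5x the nominal interval
    clipped_count: int  # samples at or beyond logger full scale (|a| >= 16 g)


@dataclass
class AccelTrace:
    """One bird-deployment's time-ordered tri-axial acceleration samples.

    ``t`` is seconds since deployment start, strictly increasing.  The
    calendar date of any sample is derived from ``t`` plus
    ``deployment_start`` (local civil time); without a deployment start
    the "date" is the elapsed-day index, which preserves the day grouping
    needed downstream.
    """

    bird_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float = 50.0
    deployment_start: Optional[datetime] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not self.bird_id:
            raise TraceError("bird_id must be non-empty")
        n = self.t.size
        if n == 0:
            raise TraceError("trace is empty")
        if not (self.x.size == self.y.size == self.z.size == n):
            raise TraceError("t, x, y, z must have equal length")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise TraceError(f"time not strictly increasing at index {idx + 1}")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def date_of(self, t_s: float):
        """Civil date (or elapsed-day index) of elapsed time ``t_s``."""
        if self.deployment_start is not None:
            return (self.deployment_start + timedelta(seconds=float(t_s))).date()
        return int(t_s // 86400.0)


def read_accel_csv(
    path,
    schema: TraceSchema = TraceSchema(),
    bird_id: Optional[str] = None,
    rate_hz: float = 50.0,
    deployment_start: Optional[datetime] = None,
) -> tuple[AccelTrace, LoadReport]:
    """Read a raw trace CSV, validating structure and dropping bad rows.

    Rows with non-finite acceleration on any axis are dropped and counted
    in the returned :class:`LoadReport`.  Non-monotone time is a hard
    error; so is an empty file or a missing mapped column.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise TraceError(f"empty trace file: {path}") from None
    for col in (schema.time, schema.x, schema.y, schema.z):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if len(df) == 0:
        raise TraceError(f"trace file has a header but no rows: {path}")

    t = pd.to_numeric(df[schema.time], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise SchemaError(f"time column {schema.time!r} is not fully parseable")
    xyz = np.column_stack(
        [
            pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
            for c in (schema.x, schema.y, schema.z)
        ]
    )
    if schema.units == "ms2":
        xyz = xyz / G_PER_MS2
    elif schema.units != "g":
        raise SchemaError(f"unknown units {schema.units!r}; expected 'g' or 'ms2'")

    keep = np.all(np.isfinite(xyz), axis=1)
    n_rows = len(df)
    report = LoadReport(n_rows=n_rows, n_kept=int(keep.sum()), drop_count=int((~keep).sum()))
    t, xyz = t[keep], xyz[keep]
    if t.size == 0:
        raise TraceError(f"all rows dropped (non-finite acceleration): {path}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        idx = int(np.argmax(dt <= 0))
        raise TraceError(f"time not strictly increasing at row {idx + 1}")

    trace = AccelTrace(
        bird_id=bird_id or str(path),
        t=t,
        x=xyz[:, 0],
        y=xyz[:, 1],
        z=xyz[:, 2],
        rate_hz=rate_hz,
        deployment_start=deployment_start,
    )
    if len(trace) > 1:
        med = float(np.median(np.diff(trace.t)))
        if abs(med - 1.0 / rate_hz) > 0.1 / rate_hz:
            raise TraceError(
                f"median sampling interval {med:.4f}s deviates >10% from "
                f"nominal 1/{rate_hz:g}s"
            )
    return trace, report


def write_trace_csv(trace: AccelTrace, path, schema: TraceSchema = TraceSchema()) -> None:
    """Write a trace in the same CSV dialect that :func:`read_accel_csv` reads."""
    df = pd.DataFrame(
        {
            schema.time: trace.t,
            schema.x: trace.x,
            schema.y: trace.y,
            schema.z: trace.z,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def write_dive_table(dives: Iterable, path) -> pd.DataFrame:
    """Write per-dive records as CSV, sorted by (bird_id, start time).

    ``dives`` is any iterable of mappings or objects carrying the fields
    in :data:`DIVE_TABLE_COLUMNS`.  Returns the frame that was written.
    """
    rows = []
    for d in dives:
        if isinstance(d, dict):
            rows.append({c: d[c] for c in DIVE_TABLE_COLUMNS})
        else:
            rows.append({c: getattr(d, c) for c in DIVE_TABLE_COLUMNS})
    df = pd.DataFrame(rows, columns=DIVE_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["bird_id", "t_start_s"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def read_dive_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DIVE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dive table missing columns {missing}")
    return df


def write_bird_table(birds: Iterable, path) -> pd.DataFrame:
    rows = []
    for b in birds:
        if isinstance(b, dict):
            rows.append({c: b[c] for c in BIRD_TABLE_COLUMNS})
        else:
            rows.append(
                {
                    "bird_id": b.bird_id,
                    "n_dives": b.Rd + b.Ld,
                    "n_left": b.Ld,
                    "n_right": b.Rd,
                    "LI": b.LI,
                    "class": b.laterality,
                }
            )
    df = pd.DataFrame(rows, columns=BIRD_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values("bird_id", kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


def validate_trace(trace: AccelTrace) -> QCReport:
    """Quality-control summary of a trace; reports, never raises."""
    n = len(trace)
    duration = trace.duration_s
    rate = (n - 1) / duration if duration > 0 else float("nan")
    nominal = 1.0 / trace.rate_hz
    gaps = int(np.sum(np.diff(trace.t) > 5.0 * nominal)) if n > 1 else 0
    amax = np.maximum(np.abs(trace.x), np.maximum(np.abs(trace.y), np.abs(trace.z)))
    clipped = int(np.sum(amax >= FULL_SCALE_G))
    return QCReport(
        duration_s=duration,
        effective_rate_hz=rate,
        gap_count=gaps,
        clipped_count=clipped,
    )
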