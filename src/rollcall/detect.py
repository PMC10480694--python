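"""Plunge-dive detection from the surge (x) axis.

A plunge dive produces a sustained forward deceleration (negative surge)
with large high-frequency variance as the bird strikes the water.  Dives
are therefore detected where the running 2-s mean of x drops below 0 g
while the running 2-s standard deviation of x exceeds 1.4 g; both
thresholds and the window are configurable.

Windows are trailing (causal): the statistic at sample ``i`` summarises
the ``window_s`` seconds ending at ``i``, so future samples never pull a
dive start earlier.  The first incomplete window per trace is a warm-up
region, emitted as NaN and excluded from detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

from .io import AccelTrace

__all__ = ["DetectionParams", "DiveEvent", "running_mean", "running_sd", "detect_dives"]


@dataclass(frozen=True)
class DetectionParams:
    """Threshold rule parameters.

    window_s
        Running-window length in seconds (trailing).
    mean_thresh_g
        Detection requires running mean of x strictly below this (g).
    sd_thresh_g
        Detection requires running sample SD of x strictly above this (g).
    min_gap_s
        Threshold-satisfying runs closer than this are merged into one
        event (two water entries seconds apart are one dive attempt).
    min_duration_s
        Merged runs shorter than this are discarded as noise.
    """

    window_s: float = 2.0
    mean_thresh_g: float = 0.0
    sd_thresh_g: float = 1.4
    min_gap_s: float = 10.0
    min_duration_s: float = 0.5

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.sd_thresh_g <= 0:
            raise ValueError("sd_thresh_g must be > 0")
        if self.min_gap_s < 0:
            raise ValueError("min_gap_s must be >= 0")


@dataclass(frozen=True)
class DiveEvent:
    bird_id: str
    t_start: float
    t_end: float
    peak_sd_g: float
    date: object  # calendar date, or elapsed-day index for undated traces

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")


def _window_samples(n: int, rate_hz: float, window_s: float) -> int:
    w = int(round(window_s * rate_hz))
    if w < 2:
        raise ValueError(f"window of {window_s}s at {rate_hz}Hz spans {w} < 2 samples")
    if w > n:
        raise ValueError(f"window ({w} samples) longer than series ({n})")
    return w


def running_mean(series: Sequence[float], rate_hz: float, window_s: float) -> np.ndarray:
    """Trailing running mean; warm-up (first incomplete window) is NaN."""
    s = np.asarray(series, dtype=float)
    w = _window_samples(s.size, rate_hz, window_s)
    return pd.Series(s).rolling(w, min_periods=w).mean().to_numpy()


def running_sd(series: Sequence[float], rate_hz: float, window_s: float) -> np.ndarray:
    """Trailing running sample SD (n-1 denominator); warm-up is NaN."""
    s = np.asarray(series, dtype=float)
    w = _window_samples(s.size, rate_hz, window_s)
    return pd.Series(s).rolling(w, min_periods=w).std(ddof=1).to_numpy()


def detect_dives(trace: AccelTrace, params: DetectionParams = DetectionParams()) -> List[DiveEvent]:
    """Detect plunge-dive events on a validated trace.

    Returns time-ordered, non-overlapping events; an empty list is a
    valid result (e.g. a commuting flight with no foraging).
    """
    if trace.duration_s <= params.window_s:
        raise ValueError("trace shorter than the detection window")
    rm = running_mean(trace.x, trace.rate_hz, params.window_s)
    rs = running_sd(trace.x, trace.rate_hz, params.window_s)
    cond = (rm < params.mean_thresh_g) & (rs > params.sd_thresh_g)
    cond &= np.isfinite(rm) & np.isfinite(rs)
    if not cond.any():
        return []

    # maximal runs of True
    idx = np.flatnonzero(cond)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))

    # merge runs separated by < min_gap_s
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s_i, e_i in zip(starts[1:], ends[1:]):
        if trace.t[s_i] - trace.t[merged[-1][1]] < params.min_gap_s:
            merged[-1][1] = int(e_i)
        else:
            merged.append([int(s_i), int(e_i)])

    events: List[DiveEvent] = []
    for s_i, e_i in merged:
        t0, t1 = float(trace.t[s_i]), float(trace.t[e_i])
        if t1 - t0 < params.min_duration_s:
            continue
        peak = float(np.nanmax(rs[s_i : e_i + 1]))
        events.append(
            DiveEvent(
                bird_id=trace.bird_id,
                t_start=t0,
                t_end=t1,
                peak_sd_g=peak,
                date=trace.date_of(t0),
            )
        )
    return events
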