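"""Roll-angle estimation from static acceleration.

Roll is the rotation about the longitudinal (surge) axis.  In a quasi-
static posture the accelerometer measures gravity, so roll can be read
from the lateral/vertical balance of the measured vector.  Two
conventions are supported:

``half_range`` (default)
    ``atan2(y, sqrt(x^2 + z^2)) * 180/pi``, range (-90, +90].  The
    standard accelerometer roll estimate; robust to pitch.
``full_range``
    ``atan2(y, z) * 180/pi``, range (-180, +180].  Distinguishes
    inverted postures and spans the full circle.

Negative roll is to the bird's left, positive to its right.  The choice
of convention is a recorded configuration value, not a hidden default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import DiveEvent
from .io import AccelTrace

__all__ = [
    "RollSeries",
    "PreDiveRoll",
    "EmptyPreDiveWindow",
    "roll_angle",
    "per_second_roll",
    "predive_roll",
]

CONVENTIONS = ("half_range", "full_range")


class EmptyPreDiveWindow(ValueError):
    """No samples fall in the pre-dive window; the dive cannot be scored."""


@dataclass(frozen=True)
class RollSeries:
    """Per-second roll angle series (degrees; negative = left)."""

    t: np.ndarray  # second marks (floor of sample time)
    roll_deg: np.ndarray
    convention: str = "half_range"


@dataclass(frozen=True)
class PreDiveRoll:
    """Mean roll over the 5 s preceding one dive and the resulting side."""

    dive: DiveEvent
    roll_mean_deg: float
    direction: str  # "left" or "right"
    n_samples: int
    tie: bool = False  # mean roll exactly zero; side assigned by rule


def roll_angle(x, y, z, convention: str = "half_range"):
    """Roll angle in degrees from one or many (x, y, z) samples in g.

    Accepts scalars or arrays (broadcast).  Raises on an all-zero vector,
    for which orientation is undefined.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown roll convention {convention!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any((x == 0) & (y == 0) & (z == 0)):
        raise ValueError("roll undefined for the all-zero acceleration vector")
    if convention == "half_range":
        ang = np.arctan2(y, np.hypot(x, z))
    else:
        ang = np.arctan2(y, z)
    out = np.degrees(ang)
    return float(out) if out.ndim == 0 else out


def per_second_roll(trace: AccelTrace, convention: str = "half_range") -> RollSeries:
    """Roll once per whole second, from that second's mean (x, y, z) vector.

    Averaging the raw vector before taking the angle suppresses dynamic
    (flapping) acceleration, which is close to zero-mean within a second.
    Seconds containing no samples are omitted.
    """
    sec = np.floor(trace.t).astype(np.int64)
    # group-mean each axis by second
    uniq, inv = np.unique(sec, return_inverse=True)
    counts = np.bincount(inv)
    mx = np.bincount(inv, weights=trace.x) / counts
    my = np.bincount(inv, weights=trace.y) / counts
    mz = np.bincount(inv, weights=trace.z) / counts
    return RollSeries(
        t=uniq.astype(float),
        roll_deg=np.asarray(roll_angle(mx, my, mz, convention)),
        convention=convention,
    )


def predive_roll(
    trace: AccelTrace,
    dive: DiveEvent,
    window_s: float = 5.0,
    convention: str = "half_range",
    circular: bool = False,
) -> PreDiveRoll:
    """Mean roll over the half-open window [t_start - window_s, t_start).

    The window is half-open so the dive's own first sample never
    contributes.  The side is the sign of the mean angle; an exact zero
    (a measure-zero tie on real data) is deterministically assigned
    "right" and flagged so callers can exclude it.

    ``circular=True`` uses the circular mean of per-sample angles, which
    is the safe choice under the full-range convention where angles can
    straddle the +/-180 wrap.
    """
    lo, hi = dive.t_start - window_s, dive.t_start
    sel = (trace.t >= lo) & (trace.t < hi)
    n = int(sel.sum())
    if n == 0:
        raise EmptyPreDiveWindow(
            f"no samples in [{lo:.2f}, {hi:.2f}) for dive at t={dive.t_start:.2f}"
        )
    ang = np.asarray(roll_angle(trace.x[sel], trace.y[sel], trace.z[sel], convention))
    if circular:
        rad = np.radians(ang)
        mean = math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    else:
        mean = float(np.mean(ang))
    tie = mean == 0.0
    direction = "left" if mean < 0 else "right"
    return PreDiveRoll(
        dive=dive, roll_mean_deg=mean, direction=direction, n_samples=n, tie=tie
    )
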