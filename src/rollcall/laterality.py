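"""Per-bird lateralization index, handedness classes and population stats.

The lateralization index (LI) for an individual with ``Rd`` right-roll
and ``Ld`` left-roll dives is

    LI = (Rd - Ld) / (Rd + Ld)                 in [-1, 1]

LI = -1 means every dive rolled left; +1 every dive rolled right.  A
bird is classified right-biased when LI > 0.25, left-biased when
LI < -0.25, and non-lateralized ("neither") when |LI| <= 0.25.

Also provided: the Wilcoxon rank-sum comparison of LI between groups
(e.g. sexes), Cohen's h for two proportions, and the normal-
approximation power of the one-sample two-proportion test used for
post-hoc power analysis of the left/right split.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BirdLaterality",
    "PowerAnalysis",
    "RankSumResult",
    "lateralization_index",
    "classify_laterality",
    "bird_laterality",
    "population_summary",
    "cohens_h",
    "power_two_proportions",
    "rank_sum_test",
]

CLASSES = ("left", "right", "neither")

#: |LI| above this (strictly) is lateralized.
LI_THRESHOLD = 0.25

#: Birds with fewer dives than this are flagged low-confidence.
MIN_DIVES_CONFIDENT = 5


@dataclass(frozen=True)
class BirdLaterality:
    bird_id: str
    Rd: int
    Ld: int
    LI: float
    laterality: str  # one of CLASSES
    low_confidence: bool = False  # fewer than MIN_DIVES_CONFIDENT dives


@dataclass(frozen=True)
class PowerAnalysis:
    h: float
    n: int
    alpha: float
    power: float


@dataclass(frozen=True)
class RankSumResult:
    W: float
    p: float


def lateralization_index(Rd: int, Ld: int) -> float:
    """(Rd - Ld) / (Rd + Ld), exact rational arithmetic before float."""
    if Rd < 0 or Ld < 0:
        raise ValueError("dive counts must be non-negative")
    if Rd + Ld == 0:
        raise ValueError("LI undefined for a bird with zero classified dives")
    return float(Fraction(Rd - Ld, Rd + Ld))


def classify_laterality(LI: float, threshold: float = LI_THRESHOLD) -> str:
    if not -1.0 <= LI <= 1.0:
        raise ValueError(f"LI must lie in [-1, 1], got {LI}")
    if LI > threshold:
        return "right"
    if LI < -threshold:
        return "left"
    return "neither"


def bird_laterality(
    bird_id: str,
    directions: Sequence[str],
    exclude_ties: Iterable[bool] = (),
    min_dives: int = MIN_DIVES_CONFIDENT,
    threshold: float = LI_THRESHOLD,
) -> BirdLaterality:
    """Build a bird's laterality record from its per-dive sides.

    ``directions`` holds "left"/"right" per dive; dives whose matching
    entry in ``exclude_ties`` is True (mean roll exactly zero) are
    excluded from the counts.
    """
    ties = list(exclude_ties) or [False] * len(directions)
    kept = [d for d, t in zip(directions, ties) if not t]
    Rd = sum(1 for d in kept if d == "right")
    Ld = sum(1 for d in kept if d == "left")
    li = lateralization_index(Rd, Ld)
    return BirdLaterality(
        bird_id=bird_id,
        Rd=Rd,
        Ld=Ld,
        LI=li,
        laterality=classify_laterality(li, threshold=threshold),
        low_confidence=(Rd + Ld) < min_dives,
    )


def population_summary(birds: Sequence[BirdLaterality] | Mapping[str, int]) -> Dict:
    """Class counts and integer-rounded percentages for a population.

    Accepts either BirdLaterality records or a pre-computed mapping of
    class -> count (useful for published tallies).
    """
    if isinstance(birds, Mapping):
        counts = {c: int(birds.get(c, 0)) for c in CLASSES}
        total_dives = None
    else:
        if len(birds) == 0:
            raise ValueError("population_summary needs at least one bird")
        tally = Counter(b.laterality for b in birds)
        counts = {c: tally.get(c, 0) for c in CLASSES}
        total_dives = int(sum(b.Rd + b.Ld for b in birds))
    n = sum(counts.values())
    if n == 0:
        raise ValueError("population_summary needs at least one bird")
    # round-half-up for deterministic reporting
    pct = {c: int(math.floor(100.0 * counts[c] / n + 0.5)) for c in CLASSES}
    out = {"counts": counts, "percent": pct, "n_birds": n}
    if total_dives is not None:
        out["total_dives"] = total_dives
    return out


def cohens_h(p1: float, p2: float) -> float:
    """Effect size for two proportions: 2*asin(sqrt(p1)) - 2*asin(sqrt(p2))."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))


def power_two_proportions(h: float, n: int, alpha: float = 0.05) -> PowerAnalysis:
    """Power of the two-sided one-sample proportions test at effect h, size n.

    Normal approximation: power = Phi(|h|*sqrt(n) - z) + Phi(-|h|*sqrt(n) - z)
    with z the two-sided critical value.  Monotone increasing in |h| and n;
    equals alpha at h = 0.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    s = abs(h) * math.sqrt(n)
    power = float(stats.norm.cdf(s - z) + stats.norm.cdf(-s - z))
    return PowerAnalysis(h=h, n=int(n), alpha=alpha, power=power)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample has <= 20 values
    and no ties; otherwise the normal approximation with tie correction.
    W is the rank sum of the first group.  Two identical constant groups
    carry no ordering information and return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if np.ptp(combined) == 0.0:
        # all values tied: the statistic is at its null mean, p = 1
        return RankSumResult(W=n1 * (n1 + n2 + 1) / 2.0, p=1.0)
    method = "exact" if (n1 + n2 <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    W = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U1 -> rank sum of group a
    return RankSumResult(W=W, p=float(min(res.pvalue, 1.0)))
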