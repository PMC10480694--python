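"""Repeatability (intraclass correlation) with bootstrap and permutation
inference.

Repeatability of a grouping factor g is the fraction of total variance
attributable to it,

    R_g = var_g / (var_id + var_date + var_resid),

computed from the variance components of a crossed random-intercept
mixed model.  For the binomial (roll-direction) family the residual
variance is the logistic link variance pi^2/3 and R is on the latent
(link) scale; an observed-scale version is available as a secondary
output.

Uncertainty comes from a parametric bootstrap (simulate responses from
the fitted model, refit, collect R) and significance from a permutation
scheme that shuffles the group labels across observations, destroying
individual structure while preserving the marginal response
distribution.  A boundary-corrected likelihood-ratio test against the
model without the focal random effect is provided as a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .mixedmodels import (
    LINK_VARIANCE_LOGIT,
    VarianceComponents,
    fit_binomial_crossed,
    fit_gaussian_crossed,
)

__all__ = [
    "ModelSpec",
    "RepeatabilityResult",
    "repeatability_from_vc",
    "observed_scale_repeatability",
    "bootstrap_ci",
    "permutation_p",
    "lrt_compare",
    "repeatability_analysis",
]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one repeatability model."""

    family: str  # "gaussian" | "binomial"
    response: str
    random: Tuple[str, ...] = ("bird_id", "date")
    fixed: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 1 <= len(self.random) <= 2:
            raise ValueError("one or two random factors are supported")

    def fit(self, df: pd.DataFrame) -> VarianceComponents:
        if self.family == "gaussian":
            return fit_gaussian_crossed(
                df, response=self.response, random=self.random, fixed=self.fixed
            )
        return fit_binomial_crossed(
            df, response=self.response, random=self.random, fixed=self.fixed
        )

    def drop_random(self, term: str) -> "ModelSpec":
        if term not in self.random:
            raise ValueError(f"{term!r} not among random terms {self.random}")
        remaining = tuple(r for r in self.random if r != term)
        if not remaining:
            raise ValueError("cannot drop the only random term")
        return ModelSpec(self.family, self.response, remaining, self.fixed)


@dataclass
class RepeatabilityResult:
    R: float
    se: Optional[float]
    ci: Optional[Tuple[float, float]]
    p: Optional[float]
    group: str  # "id" or "date"
    n_obs: int
    n_birds: int
    vc: VarianceComponents = field(repr=False, default=None)
    p_lrt: Optional[float] = None
    n_boot: int = 0
    n_perm: int = 0
    seed: Optional[int] = None


def repeatability_from_vc(vc: VarianceComponents, group: str = "id") -> float:
    """R = var_group / (var_id + var_date + var_resid).

    For a binomial fit this is the latent-scale repeatability.  Raises
    if every component is zero (R undefined; degenerate response).
    """
    total = vc.total_variance
    if total <= 0.0:
        raise ValueError("repeatability undefined: all variance components are zero")
    if group == "id":
        return vc.var_id / total
    if group == "date":
        return vc.var_date / total
    raise ValueError(f"group must be 'id' or 'date', got {group!r}")


def observed_scale_repeatability(vc: VarianceComponents, n_nodes: int = 61) -> float:
    """Observed(original)-scale repeatability for a binomial fit.

    Integrates the logistic mean over the Gaussian random effects by
    Gauss-Hermite quadrature: with p(u) = expit(b0 + u), the among-group
    variance of p over u ~ N(0, var_id + var_date) is set against the
    total Bernoulli variance of the marginal probability.
    """
    if vc.family != "binomial":
        raise ValueError("observed-scale repeatability applies to binomial fits")
    b0 = vc.fixed_effects.get("(Intercept)", 0.0)
    s2 = vc.var_id + vc.var_date
    if s2 <= 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / math.sqrt(2.0 * math.pi)
    p = expit(b0 + math.sqrt(s2) * nodes)
    m = float(w @ p)
    var_among = float(w @ (p - m) ** 2)
    frac_id = vc.var_id / s2
    return frac_id * var_among / (m * (1.0 - m))


# ---------------------------------------------------------------------------
# Parametric bootstrap & permutation
# ---------------------------------------------------------------------------


def _simulate_from_fit(
    df: pd.DataFrame, spec: ModelSpec, vc: VarianceComponents, rng: np.random.Generator
) -> np.ndarray:
    """Draw one synthetic response vector from the fitted model."""
    n = len(df)
    eta = np.full(n, vc.fixed_effects.get("(Intercept)", 0.0))
    # rebuild the fixed-effect contribution with the stored coefficients
    for f in spec.fixed:
        dummies = pd.get_dummies(df[f].astype("category"), drop_first=True, dtype=float)
        for c in dummies.columns:
            coef = vc.fixed_effects.get(f"{f}[{c}]", 0.0)
            eta += coef * dummies[c].to_numpy()
    term_var = {0: vc.var_id, 1: vc.var_date}
    for k, r in enumerate(spec.random):
        codes, levels = pd.factorize(df[r], sort=True)
        u = rng.normal(0.0, math.sqrt(max(term_var[k], 0.0)), size=len(levels))
        eta += u[codes]
    if spec.family == "gaussian":
        return eta + rng.normal(0.0, math.sqrt(vc.var_resid), size=n)
    return (rng.random(n) < expit(eta)).astype(float)


def bootstrap_ci(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    group: str = "id",
    vc: Optional[VarianceComponents] = None,
):
    """Parametric-bootstrap SE and 95% percentile CI for R.

    Simulates responses from the fitted model, refits, and collects R.
    Returns (se, (lo, hi), R_draws).  Reproducible under a fixed seed;
    more than 10% failed replicates triggers a warning carrying the
    effective count.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be a positive integer")
    if vc is None:
        vc = spec.fit(df)
    if not vc.converged:
        raise RuntimeError("base model did not converge; bootstrap would be meaningless")
    rng = np.random.default_rng(seed)
    work = df.copy()
    draws = []
    failed = 0
    for _ in range(n_boot):
        work[spec.response] = _simulate_from_fit(df, spec, vc, rng)
        try:
            fit = spec.fit(work)
            draws.append(repeatability_from_vc(fit, group=group))
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failed += 1
    if failed > 0.1 * n_boot:
        warnings.warn(
            f"bootstrap: {failed}/{n_boot} replicates failed; "
            f"effective replicate count {n_boot - failed}",
            stacklevel=2,
        )
    draws = np.asarray(draws)
    se = float(np.std(draws, ddof=1)) if draws.size > 1 else float("nan")
    ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    return se, ci, draws


def permutation_p(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    group: str = "id",
    vc: Optional[VarianceComponents] = None,
) -> float:
    """Permutation p-value for R > 0.

    Shuffles the focal grouping labels across observations (breaking
    individual structure while preserving the marginal response), refits
    and compares:  p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be a positive integer")
    if vc is None:
        vc = spec.fit(df)
    r_obs = repeatability_from_vc(vc, group=group)
    col = spec.random[0] if group == "id" else spec.random[1]
    rng = np.random.default_rng(seed)
    labels = df[col].to_numpy()
    work = df.copy()
    n_ge = 0
    n_done = 0
    for _ in range(n_perm):
        work[col] = rng.permutation(labels)
        try:
            fit = spec.fit(work)
            r_perm = repeatability_from_vc(fit, group=group)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            continue
        n_done += 1
        if r_perm >= r_obs:
            n_ge += 1
    if n_done < 0.9 * n_perm:
        warnings.warn(
            f"permutation: only {n_done}/{n_perm} replicates usable", stacklevel=2
        )
    return (1.0 + n_ge) / (1.0 + n_done)


def lrt_compare(full: VarianceComponents, reduced: VarianceComponents):
    """Likelihood-ratio test of a variance component on the boundary.

    The reduced model must be nested in the full model (same family,
    response and fixed effects; random terms a strict subset).  The
    reference distribution for a single variance component tested on
    the boundary is the 50:50 mixture of chi2_0 and chi2_1.  Returns
    (statistic, p).
    """
    same = (
        full.family == reduced.family
        and full.response == reduced.response
        and full.fixed_terms == reduced.fixed_terms
        and full.method == reduced.method
    )
    nested = set(reduced.random_terms) <= set(full.random_terms)
    if not (same and nested):
        raise ValueError("models are not nested; cannot form a likelihood ratio")
    stat = 2.0 * (full.loglik - reduced.loglik)
    stat = max(stat, 0.0)
    if stat <= 0.0:
        return 0.0, 1.0
    p = 0.5 * float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def repeatability_analysis(
    df: pd.DataFrame,
    spec: ModelSpec,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    group: str = "id",
) -> RepeatabilityResult:
    """Fit, bootstrap and permutation-test one repeatability model."""
    vc = spec.fit(df)
    r = repeatability_from_vc(vc, group=group)
    se = ci = p = p_lrt = None
    if n_boot > 0:
        se, ci, _ = bootstrap_ci(df, spec, n_boot=n_boot, seed=seed, group=group, vc=vc)
    if n_perm > 0:
        perm_seed = None if seed is None else seed + 1
        p = permutation_p(df, spec, n_perm=n_perm, seed=perm_seed, group=group, vc=vc)
    if len(spec.random) == 2:
        term = spec.random[0] if group == "id" else spec.random[1]
        reduced = spec.drop_random(term).fit(df)
        _, p_lrt = lrt_compare(vc, reduced)
    id_col = spec.random[0]
    return RepeatabilityResult(
        R=r,
        se=se,
        ci=ci,
        p=p,
        group=group,
        n_obs=vc.n_obs,
        n_birds=vc.n_groups.get(id_col, 0),
        vc=vc,
        p_lrt=p_lrt,
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
    )
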