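"""Crossed random-intercept mixed models for repeatability estimation.

Two model families, both with up to two crossed random-intercept factors
(individual and calendar day) and optional categorical fixed effects:

Gaussian (roll angle)
    y = X b + Z1 u + Z2 v + e,  u ~ N(0, s1 I), v ~ N(0, s2 I),
    e ~ N(0, se I).  Fitted by REML (ML optional), profiling the
    residual variance and the fixed effects out of the criterion and
    optimising the two variance ratios.  All linear algebra runs through
    the Woodbury identity on the q x q random-effect cross-product, so a
    fit costs O(n + q^3) per criterion evaluation and refitting
    thousands of bootstrap/permutation replicates is cheap.

Binomial (roll direction)
    logit P(y=1) = X b + Z1 u + Z2 v, fitted by the Laplace
    approximation to the integrated likelihood: for candidate variances
    the joint penalised log-likelihood is maximised over (b, u, v) by
    Newton iterations, and the marginal log-likelihood is the penalised
    optimum minus half the log-determinant of the scaled curvature.
    Birds that roll exclusively to one side (complete separation at the
    group level) are handled by the integration itself - the Gaussian
    penalty keeps their intercepts finite - and must not be dropped.

The residual variance reported for the binomial family is the logistic
link variance pi^2/3, which makes the latent-scale repeatability
R = s_group / (s1 + s2 + pi^2/3) directly comparable with the Gaussian
definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

__all__ = [
    "VarianceComponents",
    "LINK_VARIANCE_LOGIT",
    "fit_gaussian_crossed",
    "fit_binomial_crossed",
]

#: Variance of the standard logistic distribution (logit-link residual).
LINK_VARIANCE_LOGIT = math.pi**2 / 3.0

_VAR_FLOOR = 1e-8
_VAR_CEIL = 1e8


@dataclass
class VarianceComponents:
    """Fitted variance components and metadata for one mixed model."""

    var_id: float
    var_date: float
    var_resid: float
    fixed_effects: Dict[str, float]
    loglik: float
    family: str  # "gaussian" | "binomial"
    method: str  # "reml" | "ml" | "laplace"
    converged: bool
    n_obs: int
    n_groups: Dict[str, int]
    random_terms: Tuple[str, ...]
    fixed_terms: Tuple[str, ...]
    response: str
    degenerate: bool = False

    @property
    def total_variance(self) -> float:
        return self.var_id + self.var_date + self.var_resid


def _design(
    df: pd.DataFrame,
    response: str,
    random: Sequence[str],
    fixed: Sequence[str],
):
    """Response vector, fixed-effect design and random-factor codes."""
    y = np.asarray(df[response], dtype=float)
    n = y.size
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for f in fixed:
        dummies = pd.get_dummies(df[f].astype("category"), drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
            names.append(f"{f}[{c}]")
    X = np.column_stack(cols)
    factors = []
    for r in random:
        codes, levels = pd.factorize(df[r], sort=True)
        if (codes < 0).any():
            raise ValueError(f"random factor {r!r} contains missing values")
        factors.append((codes.astype(np.int64), len(levels)))
    return y, X, names, factors


# ---------------------------------------------------------------------------
# Gaussian REML/ML via Woodbury profiling
# ---------------------------------------------------------------------------


class _GaussianProfile:
    """Profiled (RE)ML criterion for the crossed Gaussian model.

    Everything that does not depend on the variance ratios is
    precomputed: X'X, X'y, y'y, the per-factor group sums of X and y,
    and the level-count cross-products between the factors.
    """

    def __init__(self, y, X, factors):
        self.n, self.p = X.shape
        self.y, self.X = y, X
        self.factors = factors
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.U = []  # Z_k' X  (q_k x p)
        self.v = []  # Z_k' y  (q_k,)
        self.counts = []
        for codes, q in factors:
            U = np.zeros((q, self.p))
            for j in range(self.p):
                U[:, j] = np.bincount(codes, weights=X[:, j], minlength=q)
            self.U.append(U)
            self.v.append(np.bincount(codes, weights=y, minlength=q))
            self.counts.append(np.bincount(codes, minlength=q).astype(float))
        if len(factors) == 2:
            (c1, q1), (c2, q2) = factors
            self.cross = np.bincount(c1 * q2 + c2, minlength=q1 * q2).reshape(q1, q2)
        else:
            self.cross = None
        self.q = sum(q for _, q in factors)
        sign, logdet = np.linalg.slogdet(self.XtX)
        self.logdet_XtX = logdet

    def _assemble(self, gammas):
        """M = I_q + Zs'Zs, Zs'X, Zs'y for scaled Z columns."""
        sq = [math.sqrt(g) for g in gammas]
        qs = [q for _, q in self.factors]
        M = np.eye(self.q)
        off = np.cumsum([0] + qs)
        for k, (g, q) in enumerate(zip(gammas, qs)):
            sl = slice(off[k], off[k + 1])
            M[sl, sl] += g * np.diag(self.counts[k])
        if len(gammas) == 2 and self.cross is not None:
            s = sq[0] * sq[1]
            M[off[0] : off[1], off[1] : off[2]] += s * self.cross
            M[off[1] : off[2], off[0] : off[1]] += s * self.cross.T
        ZsX = np.vstack([sq[k] * self.U[k] for k in range(len(gammas))])
        Zsy = np.concatenate([sq[k] * self.v[k] for k in range(len(gammas))])
        return M, ZsX, Zsy

    def solve(self, gammas):
        """GLS solve at variance ratios ``gammas``.

        Returns (beta, sigma2_reml, sigma2_ml, logdet_M, logdet_A, quad)
        where quad = r' W^-1 r at beta.
        """
        M, ZsX, Zsy = self._assemble(gammas)
        cho = np.linalg.cholesky(M)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cho))))
        MiZsX = np.linalg.solve(M, ZsX)
        MiZsy = np.linalg.solve(M, Zsy)
        A = self.XtX - ZsX.T @ MiZsX  # X' W^-1 X
        b = self.Xty - ZsX.T @ MiZsy  # X' W^-1 y
        yWy = self.yty - Zsy @ MiZsy
        beta = np.linalg.solve(A, b)
        quad = max(yWy - b @ beta, 1e-300)
        sign, logdet_A = np.linalg.slogdet(A)
        return beta, quad, logdet_M, logdet_A

    def neg_criterion(self, gammas, reml=True):
        n, p = self.n, self.p
        try:
            beta, quad, logdet_M, logdet_A = self.solve(gammas)
        except np.linalg.LinAlgError:
            return 1e12
        if reml:
            s2 = quad / (n - p)
            ll = -0.5 * (
                (n - p) * math.log(s2)
                + logdet_M
                + logdet_A
                - self.logdet_XtX
                + (n - p) * (1.0 + math.log(2.0 * math.pi))
            )
        else:
            s2 = quad / n
            ll = -0.5 * (n * math.log(s2) + logdet_M + n * (1.0 + math.log(2.0 * math.pi)))
        return -ll


def fit_gaussian_crossed(
    df: pd.DataFrame,
    response: str = "roll_angle_deg",
    random: Sequence[str] = ("bird_id", "date"),
    fixed: Sequence[str] = (),
    reml: bool = True,
) -> VarianceComponents:
    """REML (or ML) fit of the crossed random-intercept Gaussian model.

    ``random`` names one or two grouping columns; the first is treated
    as the individual ("id") term, the second as the day term.  A
    constant response yields the degenerate all-zero fit, flagged.
    """
    random = tuple(random)
    fixed = tuple(fixed)
    y, X, names, factors = _design(df, response, random, fixed)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("too few observations for the requested design")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n_groups = {r: q for r, (_, q) in zip(random, factors)}

    if float(np.var(y)) < 1e-24:
        beta = np.zeros(p)
        beta[0] = y[0]
        return VarianceComponents(
            var_id=0.0,
            var_date=0.0,
            var_resid=0.0,
            fixed_effects=dict(zip(names, beta)),
            loglik=math.inf,
            family="gaussian",
            method="reml" if reml else "ml",
            converged=True,
            n_obs=n,
            n_groups=n_groups,
            random_terms=random,
            fixed_terms=fixed,
            response=response,
            degenerate=True,
        )

    prof = _GaussianProfile(y, X, factors)
    k = len(factors)
    # moment-based start: between-level variance of factor means over a
    # pooled within guess, clipped to a sane ratio range
    resid = y - float(np.mean(y))
    s2_tot = float(np.var(resid)) or 1.0
    start = np.empty(k)
    for j, (codes, q) in enumerate(factors):
        means = np.bincount(codes, weights=resid, minlength=q) / np.maximum(
            np.bincount(codes, minlength=q), 1
        )
        start[j] = np.clip(float(np.var(means)) / s2_tot, 1e-3, 100.0)
    best = None
    success = False
    for s0 in (start, np.full(k, 0.5)):
        res = optimize.minimize(
            prof.neg_criterion,
            s0,
            args=(reml,),
            method="L-BFGS-B",
            bounds=[(0.0, 1e7)] * k,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        # a start that converged to (numerically) the same optimum
        # certifies it even if another start ended abnormally there
        if res.success and res.fun < best.fun + 1e-6:
            success = True
        if success:
            break
    # Newton polish on the profiled criterion: forward-difference
    # gradients limit L-BFGS-B to ~1e-5 in the ratios
    x, fx = best.x.copy(), best.fun
    fun = lambda g: prof.neg_criterion(np.clip(g, 0.0, 1e7), reml)
    for _ in range(3):
        h = 1e-5 * (1.0 + np.abs(x))
        grad = np.empty(k)
        hess = np.empty((k, k))
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            fp[i], fm[i] = fun(x + ei), fun(x - ei)
            grad[i] = (fp[i] - fm[i]) / (2 * h[i])
            hess[i, i] = (fp[i] - 2 * fx + fm[i]) / h[i] ** 2
        if k == 2:
            fpp = fun(x + h)
            hess[0, 1] = hess[1, 0] = (
                fpp - fp[0] - fp[1] + fx
            ) / (h[0] * h[1])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        xn = np.clip(x - step, 0.0, 1e7)
        fn = fun(xn)
        if not np.isfinite(fn) or fn > fx:
            break
        x, fx = xn, fn
        if np.max(np.abs(step)) < 1e-10:
            break
    if not success:
        # certify via first-order conditions at the polished point
        # (projected gradient: boundary coordinates may push outward)
        h = 1e-5 * (1.0 + np.abs(x))
        ok = True
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            g_i = (fun(x + ei) - fun(np.clip(x - ei, 0.0, None))) / (2 * h[i])
            if x[i] <= 1e-12:
                ok = ok and g_i > -1e-2
            else:
                ok = ok and abs(g_i) < 1e-2
        success = ok
    best.x, best.fun = x, fx
    gammas = np.clip(best.x, 0.0, None)
    beta, quad, _, _ = prof.solve(gammas)
    dof = n - p if reml else n
    s2e = quad / dof
    variances = [float(g * s2e) for g in gammas]
    var_id = variances[0]
    var_date = variances[1] if k == 2 else 0.0
    return VarianceComponents(
        var_id=var_id,
        var_date=var_date,
        var_resid=float(s2e),
        fixed_effects=dict(zip(names, beta)),
        loglik=float(-best.fun),
        family="gaussian",
        method="reml" if reml else "ml",
        converged=bool(success),
        n_obs=n,
        n_groups=n_groups,
        random_terms=random,
        fixed_terms=fixed,
        response=response,
    )


# ---------------------------------------------------------------------------
# Binomial logit GLMM via Laplace approximation
# ---------------------------------------------------------------------------


class _LaplaceLogit:
    def __init__(self, y, X, factors):
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.factors = factors
        self.qs = [q for _, q in factors]
        self.q = sum(self.qs)
        self.off = np.cumsum([0] + self.qs)
        self._warm: Optional[np.ndarray] = None  # (beta, u) from last solve

    def _eta(self, beta, u):
        eta = self.X @ beta
        for k, (codes, _) in enumerate(self.factors):
            eta = eta + u[self.off[k] : self.off[k + 1]][codes]
        return eta

    def _penalised(self, beta, u, dinv):
        eta = self._eta(beta, u)
        # log-likelihood of Bernoulli with logit link, numerically safe
        ll = float(self.y @ eta - np.sum(np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(u @ (dinv * u))

    def _newton(self, dinv, max_iter=100, tol=1e-8):
        """Maximise the penalised log-likelihood jointly over (beta, u)."""
        p, q = self.p, self.q
        if self._warm is not None:
            beta = self._warm[:p].copy()
            u = self._warm[p:].copy()
        else:
            ybar = min(max(float(np.mean(self.y)), 1e-3), 1 - 1e-3)
            beta = np.zeros(p)
            beta[0] = math.log(ybar / (1 - ybar))
            u = np.zeros(q)
        f = self._penalised(beta, u, dinv)
        converged = False
        for _ in range(max_iter):
            eta = self._eta(beta, u)
            mu = expit(eta)
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            r = self.y - mu
            g = np.empty(p + q)
            g[:p] = self.X.T @ r
            for k, (codes, qk) in enumerate(self.factors):
                sl = slice(p + self.off[k], p + self.off[k + 1])
                g[sl] = np.bincount(codes, weights=r, minlength=qk)
            g[p:] -= dinv * u
            if np.max(np.abs(g)) < tol:
                converged = True
                break
            H = self._hessian(w, dinv)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                nb, nu = beta + t * step[:p], u + t * step[p:]
                nf = self._penalised(nb, nu, dinv)
                if nf >= f - 1e-12:
                    break
                t *= 0.5
            beta, u, f = nb, nu, nf
        self._warm = np.concatenate([beta, u])
        return beta, u, f, converged

    def _zwz(self, w):
        """Z' W Z as a dense q x q matrix from factor-level sums."""
        q = self.q
        Z = np.zeros((q, q))
        for k, (codes, qk) in enumerate(self.factors):
            sl = slice(self.off[k], self.off[k + 1])
            Z[sl, sl] = np.diag(np.bincount(codes, weights=w, minlength=qk))
        if len(self.factors) == 2:
            (c1, q1), (c2, q2) = self.factors
            C = np.bincount(c1 * q2 + c2, weights=w, minlength=q1 * q2).reshape(q1, q2)
            Z[: q1, q1:] = C
            Z[q1:, :q1] = C.T
        return Z

    def _hessian(self, w, dinv):
        p, q = self.p, self.q
        H = np.zeros((p + q, p + q))
        H[:p, :p] = self.X.T @ (w[:, None] * self.X)
        H[p:, p:] = self._zwz(w) + np.diag(dinv)
        for k, (codes, qk) in enumerate(self.factors):
            B = np.zeros((qk, p))
            for j in range(p):
                B[:, j] = np.bincount(codes, weights=w * self.X[:, j], minlength=qk)
            sl = slice(p + self.off[k], p + self.off[k + 1])
            H[sl, :p] = B
            H[:p, sl] = B.T
        return H

    def laplace_loglik(self, variances):
        """Marginal log-likelihood at the given per-factor variances."""
        d = np.concatenate(
            [np.full(qk, max(v, _VAR_FLOOR)) for qk, v in zip(self.qs, variances)]
        )
        dinv = 1.0 / d
        beta, u, f, converged = self._newton(dinv)
        eta = self._eta(beta, u)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        ZWZ = self._zwz(w)
        sd = np.sqrt(d)
        M = np.eye(self.q) + (sd[:, None] * ZWZ * sd[None, :])
        sign, logdet = np.linalg.slogdet(M)
        return f - 0.5 * logdet, beta, converged


def fit_binomial_crossed(
    df: pd.DataFrame,
    response: str = "direction01",
    random: Sequence[str] = ("bird_id", "date"),
    fixed: Sequence[str] = (),
) -> VarianceComponents:
    """Laplace fit of the crossed random-intercept logit GLMM.

    The reported residual variance is the logistic link variance
    pi^2/3, so latent-scale repeatability follows the same
    variance-ratio formula as the Gaussian family.
    """
    random = tuple(random)
    fixed = tuple(fixed)
    y, X, names, factors = _design(df, response, random, fixed)
    vals = np.unique(y)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("binomial response must be coded 0/1")
    n = y.size
    n_groups = {r: q for r, (_, q) in zip(random, factors)}
    lap = _LaplaceLogit(y, X, factors)
    k = len(factors)

    def neg_ll(logv):
        variances = np.exp(np.clip(logv, math.log(_VAR_FLOOR), math.log(_VAR_CEIL)))
        ll, _, _ = lap.laplace_loglik(variances)
        return -ll

    res = optimize.minimize(
        neg_ll,
        np.zeros(k),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400},
    )
    variances = np.exp(np.clip(res.x, math.log(_VAR_FLOOR), math.log(_VAR_CEIL)))
    ll, beta, conv = lap.laplace_loglik(variances)
    var_id = float(variances[0])
    var_date = float(variances[1]) if k == 2 else 0.0
    return VarianceComponents(
        var_id=0.0 if var_id <= 2 * _VAR_FLOOR else var_id,
        var_date=0.0 if var_date <= 2 * _VAR_FLOOR else var_date,
        var_resid=LINK_VARIANCE_LOGIT,
        fixed_effects=dict(zip(names, beta)),
        loglik=float(ll),
        family="binomial",
        method="laplace",
        converged=bool(res.success and conv),
        n_obs=n,
        n_groups=n_groups,
        random_terms=random,
        fixed_terms=fixed,
        response=response,
    )
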