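import math
import warnings

import numpy as np
import pandas as pd
import pytest

from rollcall.mixedmodels import (
    LINK_VARIANCE_LOGIT,
    fit_binomial_crossed,
    fit_gaussian_crossed,
)
from rollcall.repeatability import repeatability_from_vc
from rollcall.simulate import PopulationParams, simulate_dive_records, simulate_gaussian_records


def _quadrature_loglik(records, b0, var, n_nodes=51):
    """Independent Gauss-Hermite marginal log-likelihood for the
    single-random-intercept logit model (oracle; shares no code with
    the Laplace fitter)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = weights / math.sqrt(2.0 * math.pi)
    codes, _ = pd.factorize(records["bird_id"], sort=True)
    y = records["direction01"].to_numpy(dtype=float)
    s = math.sqrt(max(var, 1e-12))
    ll = 0.0
    for g in np.unique(codes):
        yy = y[codes == g]
        eta = b0 + s * nodes
        lg = yy.sum() * eta - len(yy) * np.logaddexp(0.0, eta)
        mx = lg.max()
        ll += mx + math.log(np.sum(w * np.exp(lg - mx)))
    return ll


class TestGaussianCrossed:
    def test_recovers_generating_variances(self):
        df = simulate_gaussian_records(50, 40, var_id=9.0, var_date=0.0, var_resid=1.0, seed=0)
        vc = fit_gaussian_crossed(df, response="y")
        assert vc.converged
        assert vc.var_id == pytest.approx(9.0, rel=0.2)
        assert vc.var_resid == pytest.approx(1.0, rel=0.2)
        assert vc.var_date < 0.2

    def test_constant_response_degenerate(self):
        df = pd.DataFrame(
            {"bird_id": ["a", "a", "b", "b", "c", "c"], "date": [0, 1] * 3, "y": 2.0}
        )
        vc = fit_gaussian_crossed(df, response="y")
        assert vc.degenerate
        assert vc.var_id == vc.var_date == vc.var_resid == 0.0

    def test_balanced_one_way_matches_anova_closed_form(self):
        rng = np.random.default_rng(42)
        k, m = 12, 8
        u = rng.normal(0, 2.0, k)
        y = (u[:, None] + rng.normal(0, 1.0, (k, m))).ravel()
        df = pd.DataFrame({"bird_id": np.repeat(np.arange(k), m), "y": y})
        vc = fit_gaussian_crossed(df, response="y", random=("bird_id",))
        grp = y.reshape(k, m)
        msb = m * np.sum((grp.mean(1) - y.mean()) ** 2) / (k - 1)
        msw = np.sum((grp - grp.mean(1, keepdims=True)) ** 2) / (k * (m - 1))
        assert vc.var_id == pytest.approx((msb - msw) / m, abs=1e-6)
        assert vc.var_resid == pytest.approx(msw, abs=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        """Independent REML implementation agrees on variance components
        (log-likelihoods differ only by the constant REML normalisation)."""
        import statsmodels.formula.api as smf

        df = simulate_gaussian_records(20, 12, var_id=2.0, var_date=0.3, var_resid=1.0, seed=5)
        vc = fit_gaussian_crossed(df, response="y")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm(
                "y ~ 1",
                data=df,
                groups=np.ones(len(df)),
                vc_formula={"bird": "0 + C(bird_id)", "date": "0 + C(date)"},
            ).fit(reml=True)
        assert vc.var_id == pytest.approx(fit.vcomp[0], abs=2e-3)
        assert vc.var_date == pytest.approx(fit.vcomp[1], abs=2e-3)
        assert vc.var_resid == pytest.approx(fit.scale, abs=2e-3)
        const = 0.5 * math.log(len(df))  # 0.5*log|X'X| convention difference
        assert vc.loglik == pytest.approx(fit.llf + const, abs=1e-2)

    def test_fixed_effect_estimated(self):
        df = simulate_gaussian_records(20, 15, var_id=1.0, var_date=0.0, var_resid=1.0, seed=9)
        df["grp"] = np.where(df["bird_id"] < "bird010", "A", "B")
        df.loc[df["grp"] == "B", "y"] += 5.0
        vc = fit_gaussian_crossed(df, response="y", fixed=("grp",))
        assert vc.fixed_effects["grp[B]"] == pytest.approx(5.0, abs=1.0)

    def test_repeatability_invariant_to_affine_response(self):
        df = simulate_gaussian_records(25, 15, var_id=2.0, var_date=0.2, var_resid=1.0, seed=13)
        r1 = repeatability_from_vc(fit_gaussian_crossed(df, response="y"))
        df["y"] = 3.0 * df["y"] - 7.0
        r2 = repeatability_from_vc(fit_gaussian_crossed(df, response="y"))
        assert r1 == pytest.approx(r2, abs=1e-5)

    def test_shifting_one_bird_increases_var_id(self):
        df = simulate_gaussian_records(20, 15, var_id=1.0, var_date=0.0, var_resid=1.0, seed=17)
        base = fit_gaussian_crossed(df, response="y").var_id
        df.loc[df["bird_id"] == "bird000", "y"] += 4.0
        shifted = fit_gaussian_crossed(df, response="y").var_id
        assert shifted > base


class TestBinomialCrossed:
    def test_null_bird_variance_estimated_near_zero(self):
        pop = PopulationParams(
            n_birds=50, days_per_bird=(4, 4), dives_per_bird_day=10.0,
            var_id_logit=0.0, var_date_logit=0.0, seed=31,
        )
        rec, _ = simulate_dive_records(pop)
        vc = fit_binomial_crossed(rec, response="direction01")
        assert vc.var_id < 0.1

    def test_latent_r_half_recovered(self):
        pop = PopulationParams(
            n_birds=50, days_per_bird=(4, 4), dives_per_bird_day=10.0,
            var_id_logit=LINK_VARIANCE_LOGIT, var_date_logit=0.0, seed=0,
        )
        rec, _ = simulate_dive_records(pop)
        vc = fit_binomial_crossed(rec, response="direction01")
        assert repeatability_from_vc(vc) == pytest.approx(0.5, abs=0.07)

    def test_single_effect_agrees_with_quadrature_oracle(self):
        pop = PopulationParams(
            n_birds=10, days_per_bird=(2, 2), dives_per_bird_day=12.0,
            var_id_logit=2.0, var_date_logit=1e-9, seed=4,
        )
        rec, _ = simulate_dive_records(pop)
        vc = fit_binomial_crossed(rec, response="direction01", random=("bird_id",))
        from scipy.optimize import minimize

        res = minimize(
            lambda p: -_quadrature_loglik(rec, p[0], math.exp(p[1])),
            [0.0, 0.5],
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-11, "maxiter": 2000},
        )
        assert abs(vc.loglik - (-res.fun)) < 0.1

    def test_all_one_sided_birds_not_dropped(self):
        """Complete separation at the bird level must be handled by the
        integrated likelihood: strongly biased birds stay in the fit and
        produce a large, finite bird variance."""
        pop = PopulationParams(
            n_birds=20, days_per_bird=(2, 2), dives_per_bird_day=10.0,
            var_id_logit=50.0, var_date_logit=0.0, seed=8,
        )
        rec, _ = simulate_dive_records(pop)
        per_bird = rec.groupby("bird_id")["direction01"].mean()
        assert ((per_bird == 0) | (per_bird == 1)).any()  # separation present
        vc = fit_binomial_crossed(rec, response="direction01")
        assert np.isfinite(vc.loglik)
        assert vc.var_id > 2.0
        assert repeatability_from_vc(vc) > 0.5

    def test_invariant_to_flipping_response_coding(self, small_records):
        rec, _ = small_records
        vc1 = fit_binomial_crossed(rec, response="direction01")
        rec = rec.assign(direction01=1 - rec["direction01"])
        vc2 = fit_binomial_crossed(rec, response="direction01")
        assert repeatability_from_vc(vc1) == pytest.approx(
            repeatability_from_vc(vc2), abs=1e-3
        )

    def test_link_variance_reported_as_residual(self, small_records):
        rec, _ = small_records
        vc = fit_binomial_crossed(rec, response="direction01")
        assert vc.var_resid == pytest.approx(math.pi**2 / 3.0)

    def test_non_binary_response_rejected(self):
        df = pd.DataFrame({"bird_id": list("aabb"), "date": [0, 1, 0, 1], "y": [0, 1, 2, 1]})
        with pytest.raises(ValueError, match="0/1"):
            fit_binomial_crossed(df, response="y")
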