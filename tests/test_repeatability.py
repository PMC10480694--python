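import math

import numpy as np
import pandas as pd
import pytest

from rollcall.mixedmodels import LINK_VARIANCE_LOGIT, fit_gaussian_crossed
from rollcall.repeatability import (
    ModelSpec,
    bootstrap_ci,
    lrt_compare,
    observed_scale_repeatability,
    permutation_p,
    repeatability_analysis,
    repeatability_from_vc,
)
from rollcall.simulate import simulate_gaussian_records


def _vc(var_id, var_date, var_resid, family="gaussian", random=("bird_id", "date")):
    from rollcall.mixedmodels import VarianceComponents

    return VarianceComponents(
        var_id=var_id,
        var_date=var_date,
        var_resid=var_resid,
        fixed_effects={"(Intercept)": 0.0},
        loglik=0.0,
        family=family,
        method="reml",
        converged=True,
        n_obs=100,
        n_groups={"bird_id": 10, "date": 5},
        random_terms=random,
        fixed_terms=(),
        response="y",
    )


class TestRepeatabilityFromVc:
    def test_gaussian_closed_form(self):
        assert repeatability_from_vc(_vc(3.0, 0.0, 1.0)) == pytest.approx(0.75)

    def test_zero_group_variance(self):
        assert repeatability_from_vc(_vc(0.0, 0.5, 1.0)) == 0.0

    def test_binomial_latent_scale_half(self):
        vc = _vc(LINK_VARIANCE_LOGIT, 0.0, LINK_VARIANCE_LOGIT, family="binomial")
        assert repeatability_from_vc(vc) == pytest.approx(0.5)

    def test_date_group(self):
        assert repeatability_from_vc(_vc(3.0, 1.0, 0.0), group="date") == pytest.approx(0.25)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            repeatability_from_vc(_vc(0.0, 0.0, 0.0))


def test_observed_scale_below_latent_scale():
    vc = _vc(2.0, 0.0, LINK_VARIANCE_LOGIT, family="binomial")
    r_obs = observed_scale_repeatability(vc)
    r_lat = repeatability_from_vc(vc)
    assert 0.0 < r_obs < r_lat


class TestBootstrap:
    SPEC = ModelSpec("gaussian", "y")

    def test_zero_replicates_rejected(self):
        df = simulate_gaussian_records(10, 8, 1.0, 0.1, 1.0, seed=1)
        with pytest.raises(ValueError):
            bootstrap_ci(df, self.SPEC, n_boot=0)

    def test_same_seed_identical_ci(self):
        df = simulate_gaussian_records(15, 10, 1.0, 0.1, 1.0, seed=2)
        a = bootstrap_ci(df, self.SPEC, n_boot=20, seed=7)
        b = bootstrap_ci(df, self.SPEC, n_boot=20, seed=7)
        assert a[0] == b[0] and a[1] == b[1]

    def test_coverage_of_true_repeatability(self):
        """95% percentile CI covers the generating R in most replicate
        datasets (reduced replicate counts keep this tractable)."""
        true_r = 0.75
        covered = 0
        n_rep = 25
        for seed in range(n_rep):
            df = simulate_gaussian_records(25, 12, 3.0, 0.0, 1.0, seed=100 + seed)
            _, ci, _ = bootstrap_ci(df, self.SPEC, n_boot=79, seed=seed)
            if ci[0] <= true_r <= ci[1]:
                covered += 1
        assert covered >= int(0.85 * n_rep)


class TestPermutation:
    SPEC = ModelSpec("gaussian", "y")

    def test_strong_signal_attains_minimum_p(self):
        df = simulate_gaussian_records(30, 12, 4.0, 0.0, 1.0, seed=3)
        p = permutation_p(df, self.SPEC, n_perm=39, seed=4)
        assert p == pytest.approx(1.0 / 40.0)

    def test_p_bounded(self):
        df = simulate_gaussian_records(10, 6, 0.0, 0.0, 1.0, seed=5)
        p = permutation_p(df, self.SPEC, n_perm=19, seed=6)
        assert 0.0 < p <= 1.0

    def test_type_i_error_controlled_under_null(self):
        """Generated var_id = 0: nominal-5% rejections happen in at most
        ~10% of seeds."""
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = simulate_gaussian_records(20, 8, 0.0, 0.05, 1.0, seed=200 + seed)
            p = permutation_p(df, self.SPEC, n_perm=59, seed=seed)
            if p < 0.05:
                rejections += 1
        assert rejections <= 0.10 * n_seeds


class TestLRT:
    def test_identical_models_statistic_zero_p_one(self):
        df = simulate_gaussian_records(15, 10, 1.0, 0.2, 1.0, seed=7)
        vc = fit_gaussian_crossed(df, response="y")
        stat, p = lrt_compare(vc, vc)
        assert stat == 0.0
        assert p == 1.0

    def test_statistic_non_negative_and_signal_detected(self):
        df = simulate_gaussian_records(30, 12, 3.0, 0.1, 1.0, seed=8)
        full = fit_gaussian_crossed(df, response="y")
        reduced = fit_gaussian_crossed(df, response="y", random=("date",))
        stat, p = lrt_compare(full, reduced)
        assert stat >= 0.0
        assert p < 1e-6

    def test_non_nested_models_rejected(self):
        df = simulate_gaussian_records(15, 10, 1.0, 0.2, 1.0, seed=9)
        g = fit_gaussian_crossed(df, response="y")
        df["d01"] = (df["y"] > 0).astype(int)
        from rollcall.mixedmodels import fit_binomial_crossed

        b = fit_binomial_crossed(df, response="d01")
        with pytest.raises(ValueError, match="nested"):
            lrt_compare(g, b)

    def test_boundary_corrected_size_under_null(self):
        rejections = 0
        n_seeds = 40
        for seed in range(n_seeds):
            df = simulate_gaussian_records(20, 8, 0.0, 0.05, 1.0, seed=300 + seed)
            full = fit_gaussian_crossed(df, response="y")
            reduced = fit_gaussian_crossed(df, response="y", random=("date",))
            _, p = lrt_compare(full, reduced)
            if p < 0.05:
                rejections += 1
        assert rejections <= math.ceil(0.10 * n_seeds)


class TestFixedEffects:
    def test_bird_level_covariate_absorbs_individual_variance(self):
        """A fixed effect that fully explains bird differences drives
        R_id toward zero; an irrelevant one barely moves it."""
        rng = np.random.default_rng(10)
        n_birds, m = 24, 12
        grp = np.repeat(np.arange(n_birds) % 2, m)  # bird-level binary covariate
        bird = np.repeat(np.arange(n_birds), m)
        date = rng.integers(0, 10, n_birds * m)
        y = 3.0 * grp + rng.normal(0, 1.0, n_birds * m)  # bird diffs = covariate only
        df = pd.DataFrame({"bird_id": bird, "date": date, "y": y, "grp": grp})
        r_without = repeatability_from_vc(fit_gaussian_crossed(df, response="y"))
        r_with = repeatability_from_vc(
            fit_gaussian_crossed(df, response="y", fixed=("grp",))
        )
        assert r_without > 0.5
        assert r_with < 0.1

    def test_irrelevant_fixed_effect_changes_r_little(self):
        df = simulate_gaussian_records(30, 15, 3.0, 0.1, 1.0, seed=11)
        rng = np.random.default_rng(12)
        birds = df["bird_id"].unique()
        noise_cov = dict(zip(birds, rng.integers(0, 2, birds.size)))
        df["junk"] = df["bird_id"].map(noise_cov)
        r0 = repeatability_from_vc(fit_gaussian_crossed(df, response="y"))
        r1 = repeatability_from_vc(fit_gaussian_crossed(df, response="y", fixed=("junk",)))
        assert abs(r0 - r1) < 0.02


def test_repeatability_analysis_bundle(small_records):
    rec, truth = small_records
    spec = ModelSpec("binomial", "direction01")
    res = repeatability_analysis(rec, spec, n_boot=15, n_perm=19, seed=5)
    assert 0.0 <= res.R <= 1.0
    assert res.ci[0] <= res.ci[1]
    assert 0.0 < res.p <= 1.0
    assert res.p_lrt is not None
    assert res.n_birds == 12
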