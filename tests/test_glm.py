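"""Cognitive-score PCA, design matrices, OLS, sign-flip max-statistic test."""

import numpy as np
import pandas as pd
import pytest

from netstates.glm import (
    SignFlipMaxStatGLM,
    build_design,
    fit_glm,
    maxstat_signflip_test,
    reduce_scores_pca,
)
from netstates.simulate import (
    CohortConfig,
    StateSpec,
    simulate_cognitive_scores,
    simulate_covariates,
)


def _covariates(n=100, seed=0):
    cfg = CohortConfig(
        n_subjects=n, n_parcels=1, n_samples=1,
        state_specs=[StateSpec([0.0], [0.0])],
        base_transition_matrix=np.array([[1.0]]),
    )
    return simulate_covariates(cfg, np.random.default_rng(seed))


class TestReduceScoresPCA:
    def test_perfectly_correlated_tasks(self, rng):
        t = rng.standard_normal(50)
        scores = np.stack([t, t], axis=1)
        pc1, loadings, var = reduce_scores_pca(scores)
        assert abs(loadings[0] - loadings[1]) < 1e-10
        assert var == pytest.approx(1.0)

    def test_generator_ground_truth_sign(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(18, 88, 300)
        scores = simulate_cognitive_scores(age, 8, -0.8, 0.5, rng)
        pc1, loadings, _ = reduce_scores_pca(scores)
        assert np.all(loadings > 0)
        assert np.corrcoef(pc1, age)[0, 1] < 0

    def test_column_sign_flip_convention(self, rng):
        age = np.linspace(18, 88, 100)
        scores = simulate_cognitive_scores(age, 4, -0.8, 0.3, rng)
        pc1a, la, _ = reduce_scores_pca(scores)
        pc1b, lb, _ = reduce_scores_pca(-scores)
        assert np.all(la > 0) and np.all(lb > 0)
        r_a = np.corrcoef(pc1a, age)[0, 1]
        r_b = np.corrcoef(pc1b, age)[0, 1]
        assert np.sign(r_a) == -np.sign(r_b)

    def test_constant_column_rejected(self, rng):
        scores = rng.standard_normal((20, 3))
        scores[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            reduce_scores_pca(scores)


class TestBuildDesign:
    def test_age_only_design(self):
        d = build_design(_covariates(100), "age")
        assert d.X.shape == (100, 2)
        assert d.names == ["constant", "age"]
        col = d.X[:, 1]
        assert abs(col.mean()) < 1e-10 and abs(col.std() - 1) < 1e-10

    def test_full_design_column_count(self):
        cov = _covariates(100)
        cov["cog_perf"] = reduce_scores_pca(
            cov[[c for c in cov if c.startswith("cog_")]].to_numpy()
        )[0]
        d = build_design(
            cov, "age",
            ["sex", "total_brain_vol", "gm_vol", "wm_vol", "head_size",
             "head_pos_x", "head_pos_y", "head_pos_z", "cog_perf"],
        )
        assert d.X.shape[1] == 11  # constant + age + 9 confounds

    def test_duplicated_confound_rejected(self):
        cov = _covariates(50)
        cov["tbv2"] = cov["total_brain_vol"]
        with pytest.raises(ValueError, match="collinear"):
            build_design(cov, "age", ["total_brain_vol", "tbv2"])


class TestFitGLM:
    def test_exact_fit_recovers_slope(self):
        cov = _covariates(80)
        d = build_design(cov, "age")
        y = 2.0 * d.X[:, 1]
        res = fit_glm(y[:, None], d)
        assert res.beta[1, 0] == pytest.approx(2.0, abs=1e-10)

    def test_null_features(self, rng):
        cov = _covariates(200)
        d = build_design(cov, "age")
        y = rng.standard_normal((200, 5))
        res = fit_glm(y, d)
        assert np.abs(res.beta[1]).max() < 3 / np.sqrt(200)
        assert np.abs(res.residual_variance - y.var(axis=0)).max() < 0.1

    def test_matches_normal_equations_oracle(self, rng):
        cov = _covariates(50, seed=3)
        d = build_design(cov, "age", ["sex", "total_brain_vol", "gm_vol",
                                      "wm_vol", "head_size", "head_pos_x"])
        y = rng.standard_normal((50, 4))
        res = fit_glm(y, d)
        oracle = np.linalg.pinv(d.X) @ y
        assert np.abs(res.beta - oracle).max() < 1e-8
        # residual orthogonality
        assert np.abs(d.X.T @ res.residuals).max() < 1e-8


class TestMaxStatSignFlip:
    CONFOUNDS = ("sex", "total_brain_vol", "gm_vol", "wm_vol", "head_size")

    def test_planted_effect_detected_nulls_not(self, rng):
        cov = _covariates(60, seed=5)
        d = build_design(cov, "age", self.CONFOUNDS)
        y = rng.standard_normal((60, 20))
        y[:, 7] += 5.0 * d.X[:, d.interest_index]
        res = maxstat_signflip_test(y, d, n_perm=500, seed=1)
        assert res.pvalues[7] < 0.05 and res.beta[7] > 0
        assert res.significant.sum() - res.significant[7] <= 1

    def test_constant_target_all_null(self):
        cov = _covariates(40, seed=6)
        d = build_design(cov, "age")
        res = maxstat_signflip_test(np.ones((40, 3)), d, n_perm=100, seed=0)
        assert np.allclose(res.observed, 0.0)
        assert np.all(res.pvalues == 1.0)

    def test_family_wise_error_calibrated(self):
        from netstates.experiments import fwe_calibration

        res = fwe_calibration(seed=101, n_repeats=100, n_perm=300)
        assert res["ci_low"] <= res["rate"] <= res["ci_high"]

    def test_confound_regression_removes_spurious_effect(self):
        # y driven purely by a confound correlated with age: including the
        # confound must kill the apparent age effect
        hits_with, beta_with, beta_without = 0, [], []
        for s in range(20):
            cov = _covariates(80, seed=100 + s)
            rng = np.random.default_rng(200 + s)
            y = (2.0 * (cov["total_brain_vol"] - cov["total_brain_vol"].mean())
                 / cov["total_brain_vol"].std()).to_numpy()[:, None]
            y = y + 0.5 * rng.standard_normal((80, 1))
            d_with = build_design(cov, "age", ["total_brain_vol"])
            d_without = build_design(cov, "age")
            r_with = maxstat_signflip_test(y, d_with, 300, seed=s)
            r_without = maxstat_signflip_test(y, d_without, 300, seed=s)
            beta_with.append(abs(r_with.beta[0]))
            beta_without.append(abs(r_without.beta[0]))
            hits_with += r_with.pvalues[0] >= 0.05
        assert np.mean(beta_with) < np.mean(beta_without)
        assert hits_with >= 18  # p > 0.05 in >= 90% of seeds

    def test_beta_and_t_agree_on_homoscedastic_toy(self, rng):
        cov = _covariates(60, seed=9)
        d = build_design(cov, "age", self.CONFOUNDS)
        y = rng.standard_normal((60, 10))
        y[:, 2] += 1.5 * d.X[:, d.interest_index]
        rb = maxstat_signflip_test(y, d, 400, stat="beta", seed=3)
        rt = maxstat_signflip_test(y, d, 400, stat="t", seed=3)
        assert np.array_equal(rb.significant, rt.significant)

    def test_missing_values_dropped_per_feature(self, rng):
        cov = _covariates(60, seed=11)
        d = build_design(cov, "age", self.CONFOUNDS)
        y = rng.standard_normal((60, 4))
        y[:5, 2] = np.nan
        res = maxstat_signflip_test(y, d, 200, seed=4)
        assert res.n_dropped == {2: 5}
        assert np.isfinite(res.observed).all()

    def test_estimator_wrapper(self, rng):
        cov = _covariates(50, seed=12)
        y = rng.standard_normal((50, 6))
        est = SignFlipMaxStatGLM(
            interest="age", confounds=self.CONFOUNDS, n_perm=200, random_state=0
        ).fit(cov, y)
        assert est.pvalues_.shape == (6,)
        assert est.design_.names[0] == "constant"
        # sklearn get_params round-trip
        assert est.get_params()["n_perm"] == 200
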