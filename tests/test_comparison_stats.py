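"""Correlation, concordance, dependent-correlation, quintile-model, and
Wald-comparison layer, checked against closed forms and light simulations
(the heavier calibrations run in the acceptance suite)."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dietmetrics import (
    assign_quintiles, concordance_correlation, fit_quintile_model,
    per_sd_association, spearman_matrix, wald_trend_difference,
    wolfe_dependent_correlation_test,
)


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unit_correlation(self):
        x = np.linspace(0, 3, 30)
        df = pd.DataFrame({"x": x, "y": np.exp(x), "z": -x})
        r, p = spearman_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(r.values, r.values.T)

    def test_hand_rank_example(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4] * 3, "y": [2, 1, 4, 3] * 3})
        r, _ = spearman_matrix(df, min_n=10)
        assert r.loc["x", "y"] == pytest.approx(0.6)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"x": np.arange(20.0), "c": np.ones(20)})
        r, p = spearman_matrix(df)
        assert np.isnan(r.loc["x", "c"]) and np.isnan(p.loc["x", "c"])


class TestConcordance:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert concordance_correlation(x, x) == pytest.approx(1.0)

    def test_shift_example_closed_form(self):
        assert concordance_correlation(np.array([1.0, 2, 3]),
                                       np.array([2.0, 3, 4])) == pytest.approx(4 / 7)

    def test_ccc_never_exceeds_absolute_pearson(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 30)
            y = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 30)
            ccc = concordance_correlation(x, y)
            assert abs(ccc) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12


def permutation_oracle_p(x1, x2, y, n_perm=2000, seed=0):
    """Within-subject label-swap permutation test for equality of the two
    dependent rank correlations (the binding oracle for the analytic test)."""
    from scipy.stats import rankdata
    rng = np.random.default_rng(seed)
    n = len(y)
    z1 = rankdata(x1); z2 = rankdata(x2); zy = rankdata(y)
    z1 = (z1 - z1.mean()) / z1.std(); z2 = (z2 - z2.mean()) / z2.std()
    zy = (zy - zy.mean()) / zy.std()
    d = z1 - z2
    def corr(dv):
        dc = dv - dv.mean()
        s = dc.std()
        return 0.0 if s == 0 else float((dc * zy).mean() / s)
    observed = abs(corr(d))
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perms = signs * d
    centered = perms - perms.mean(axis=1, keepdims=True)
    sds = centered.std(axis=1)
    stats_perm = np.abs((centered * zy).mean(axis=1) / np.where(sds == 0, np.inf, sds))
    return float((np.sum(stats_perm >= observed - 1e-12) + 1) / (n_perm + 1))


class TestWolfeTest:
    def test_identical_metrics_give_p_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 1, 50)
        res = wolfe_dependent_correlation_test(x, x, y)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_detects_clear_correlation_difference(self):
        rng = np.random.default_rng(1)
        n = 600
        y = rng.normal(0, 1, n)
        x1 = 0.8 * y + rng.normal(0, 0.6, n)
        x2 = rng.normal(0, 1, n)
        res = wolfe_dependent_correlation_test(x1, x2, y)
        assert res.p_value < 1e-6 and res.r_a > res.r_b

    def test_size_close_to_nominal_under_null(self):
        """Light H0 calibration (the 2000-rep version runs in acceptance)."""
        rejections = 0
        reps = 400
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            L = rng.normal(0, 1, 200)
            x1 = L + rng.normal(0, 1.2, 200)
            x2 = L + rng.normal(0, 1.2, 200)
            y = 0.35 * L + rng.normal(0, 1, 200)
            if wolfe_dependent_correlation_test(x1, x2, y).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_agrees_with_permutation_oracle(self):
        for rep in range(5):
            rng = np.random.default_rng(50 + rep)
            L = rng.normal(0, 1, 150)
            x1 = L + rng.normal(0, 1, 150)
            x2 = 0.6 * L + rng.normal(0, 1, 150)
            y = 0.4 * L + rng.normal(0, 1, 150)
            analytic = wolfe_dependent_correlation_test(x1, x2, y).p_value
            oracle = permutation_oracle_p(x1, x2, y, seed=rep)
            assert analytic == pytest.approx(oracle, abs=0.03)


class TestAssignQuintiles:
    def test_ten_ordered_values(self):
        labels = assign_quintiles(np.arange(1, 11))
        assert labels.tolist() == [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]

    def test_all_tied_values_share_middle_label(self):
        assert set(assign_quintiles(np.ones(10))) == {3}

    def test_order_equivariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 101)
        perm = rng.permutation(101)
        assert (assign_quintiles(x)[perm] == assign_quintiles(x[perm])).all()

    def test_balanced_partition_without_ties(self):
        rng = np.random.default_rng(3)
        labels = assign_quintiles(rng.normal(0, 1, 503))
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1


class TestQuintileModel:
    def test_outcome_equal_to_quintile_index(self):
        q = np.tile([1, 2, 3, 4, 5], 40)
        fit = fit_quintile_model(q.astype(float), q, family="continuous")
        emms = fit.quintile_estimates.set_index("quintile")["estimate"]
        assert emms.to_numpy() == pytest.approx([1, 2, 3, 4, 5], abs=1e-10)
        assert fit.p_trend < 1e-6

    def test_covariate_column_order_invariance(self):
        rng = np.random.default_rng(4)
        n = 300
        x = rng.normal(0, 1, n)
        cov = pd.DataFrame({"a": rng.normal(0, 1, n), "b": rng.normal(2, 3, n)})
        y = x + 0.5 * cov["a"].to_numpy() + rng.normal(0, 1, n)
        q = assign_quintiles(x)
        f1 = fit_quintile_model(y, q, covariates=cov)
        f2 = fit_quintile_model(y, q, covariates=cov[["b", "a"]])
        assert f1.trend_coefficient == pytest.approx(f2.trend_coefficient)
        pd.testing.assert_frame_equal(f1.quintile_estimates, f2.quintile_estimates)

    def test_affine_covariate_recoding_invariance(self):
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(0, 1, n)
        cov = pd.DataFrame({"a": rng.normal(0, 1, n)})
        y = x + cov["a"].to_numpy() + rng.normal(0, 1, n)
        q = assign_quintiles(x)
        f1 = fit_quintile_model(y, q, covariates=cov)
        f2 = fit_quintile_model(y, q, covariates=cov * 3.0 + 11.0)
        assert f1.trend_coefficient == pytest.approx(f2.trend_coefficient)
        assert f1.p_trend == pytest.approx(f2.p_trend)
        pd.testing.assert_frame_equal(f1.quintile_estimates, f2.quintile_estimates,
                                      atol=1e-8)

    def test_binary_family_q1_reference_and_or_direction(self):
        rng = np.random.default_rng(6)
        n = 2000
        x = rng.normal(0, 1, n)
        logit = -0.5 - 0.5 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        fit = fit_quintile_model(y, assign_quintiles(x), family="binary")
        est = fit.quintile_estimates.set_index("quintile")["estimate"]
        assert est[1] == 1.0
        assert est[5] < 1.0              # protective metric
        assert fit.p_trend < 0.01

    def test_null_trend_p_roughly_uniform(self):
        """Light null calibration (full 1000-rep version in acceptance)."""
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(2000 + rep)
            x = rng.normal(0, 1, 200)
            y = rng.normal(0, 1, 200)
            fit = fit_quintile_model(y, assign_quintiles(x))
            hits += fit.p_trend < 0.05
        assert 0.015 <= hits / reps <= 0.1


class TestPerSD:
    def test_outcome_equal_to_metric(self):
        rng = np.random.default_rng(7)
        x = rng.normal(10, 3, 200)
        res = per_sd_association(x, x)
        assert res.estimate == pytest.approx(np.std(x, ddof=1))

    def test_unit_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2, 300)
        y = 0.4 * x + rng.normal(0, 1, 300)
        a = per_sd_association(y, x)
        b = per_sd_association(y, 2 * x)
        assert a.estimate == pytest.approx(b.estimate)
        assert a.p_value == pytest.approx(b.p_value)

    def test_slope_coverage_over_replicates(self):
        covered = 0
        for rep in range(100):
            rng = np.random.default_rng(3000 + rep)
            x = rng.normal(0, 1, 300)
            y = 0.5 * x + rng.normal(0, 1, 300)
            res = per_sd_association(y, x)
            true_per_sd = 0.5 * 1.0 * np.std(x, ddof=1) / np.std(x, ddof=1)
            if res.ci_low <= 0.5 * np.std(x, ddof=1) <= res.ci_high:
                covered += 1
        assert covered >= 90


class TestWaldTrendDifference:
    def test_identical_metrics(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        res = wald_trend_difference(y, x, x.copy(), n_boot=50, rng=0)
        assert res.delta == 0.0 and res.p_value == 1.0

    def test_power_against_clearly_different_trends(self):
        hits = 0
        reps = 60
        for rep in range(reps):
            rng = np.random.default_rng(4000 + rep)
            n = 600
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n)
            y = 0.5 * a + rng.normal(0, 1, n)
            res = wald_trend_difference(y, a, b, n_boot=200, rng=rep)
            hits += res.p_value < 0.05
        assert hits / reps > 0.9

    def test_calibration_under_equal_trends(self):
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            n = 300
            L = rng.normal(0, 1, n)
            a = L + rng.normal(0, 1, n)
            b = L + rng.normal(0, 1, n)
            y = 0.3 * L + rng.normal(0, 1, n)
            res = wald_trend_difference(y, a, b, n_boot=200, rng=rep)
            hits += res.p_value < 0.05
        assert 0.02 <= hits / reps <= 0.1

    def test_statsmodels_agrees_with_internal_solver_on_trend(self):
        rng = np.random.default_rng(10)
        n = 400
        x = rng.normal(0, 1, n)
        y = 0.4 * x + rng.normal(0, 1, n)
        q = assign_quintiles(x).astype(float)
        res = wald_trend_difference(y, x, rng.normal(0, 1, n), n_boot=20, rng=0)
        X = sm.add_constant(pd.DataFrame({"trend": q}))
        sm_coef = sm.OLS(y, X).fit().params["trend"]
        assert res.trend_a == pytest.approx(sm_coef, rel=1e-8)
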