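"""Welch contrasts, single-covariate OLS and stepwise-AIC model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phylospat as ps
from phylospat.regression import significance_stars


def welch_oracle(a, b):
    """Independent implementation of the Welch statistic and df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_samples(self):
        c = ps.welch_t([1, 2, 3], [1, 2, 3])
        assert c.t_stat == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_worked_samples_match_oracle(self):
        a, b = [1, 2, 3, 4], [3, 4, 5, 6]
        c = ps.welch_t(a, b)
        t, df, p = welch_oracle(a, b)
        assert c.t_stat == pytest.approx(t, abs=1e-12)
        assert c.df == pytest.approx(df, abs=1e-9)
        assert c.p_value == pytest.approx(p, abs=1e-12)

    def test_swap_flips_sign_only(self):
        a, b = [1.0, 2, 3, 9], [3.0, 4, 5, 6]
        c1, c2 = ps.welch_t(a, b), ps.welch_t(b, a)
        assert c1.t_stat == pytest.approx(-c2.t_stat)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.welch_t([1.0], [1, 2, 3])

    def test_degenerate_equal_constants(self):
        c = ps.welch_t([2, 2, 2], [2, 2])
        assert (c.t_stat, c.p_value) == (0.0, 1.0)

    def test_reduces_to_pooled_when_variances_and_ns_equal(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=12)
        b = a + 3.0  # identical sample variance, same n
        w = ps.welch_t(a, b)
        p = ps.welch_t(a, b, pooled=True)
        assert w.t_stat == pytest.approx(p.t_stat, abs=1e-9)
        assert w.p_value == pytest.approx(p.p_value, abs=1e-9)

    def test_stars_convention(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.2) == ""

    def test_group_contrasts_all_pairs(self):
        rng = np.random.default_rng(1)
        groups = pd.Series(["granite"] * 10 + ["rhyolite"] * 10 + ["quartz sandstone"] * 10)
        values = pd.Series(np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 10),
                                           rng.normal(0, 1, 10)]))
        tab = ps.group_contrasts(values, groups)
        assert len(tab) == 3  # C(3,2)
        strong = tab[(tab.group_a == "granite") & (tab.group_b == "rhyolite")].iloc[0]
        assert strong.p_value < 0.01


class TestOlsR2:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = ps.ols_r2(2 * x + 1, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.params["x"] == pytest.approx(2.0)

    def test_worked_five_points_r2_is_squared_correlation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        fit = ps.ols_r2(y, x)
        assert fit.r2 == pytest.approx(float(np.corrcoef(x, y)[0, 1] ** 2), abs=1e-12)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            ps.ols_r2([1.0, 2, 3], [4.0, 4, 4])

    def test_type_one_error_calibration(self):
        """Slope p-value is uniform under the null: fraction below 0.05."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            y = rng.permutation(x) + rng.normal(size=30)
            if ps.ols_r2(y, x).pvalues["x"] < 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) < 0.02


def _candidates(rng, n):
    return pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "x3": rng.normal(size=n),
        "bedrock": rng.choice(["granite", "rhyolite", "quartz sandstone"], size=n),
    })


class TestStepwise:
    def test_true_predictor_retained(self):
        rng = np.random.default_rng(0)
        kept = 0
        for _ in range(20):
            X = _candidates(rng, 200)
            y = 5.0 * X["x1"] + rng.normal(size=200)
            fit = ps.stepwise_glm_aic(y, X)
            kept += "x1" in fit.terms
        assert kept == 20

    def test_all_noise_mostly_intercept_only(self):
        rng = np.random.default_rng(1)
        empty = 0
        for _ in range(20):
            X = _candidates(rng, 150)
            y = pd.Series(rng.normal(size=150))
            fit = ps.stepwise_glm_aic(y, X)
            empty += len(fit.terms) == 0
        assert empty > 10

    def test_duplicated_predictor_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = _candidates(rng, 100)
        X["x1_copy"] = X["x1"]
        y = 3 * X["x1"] + rng.normal(size=100)
        with pytest.warns(UserWarning, match="collinear"):
            fit = ps.stepwise_glm_aic(y, X)
        assert "x1" in fit.terms and "x1_copy" not in fit.terms

    def test_zero_gain_parameter_costs_exactly_two_aic(self):
        """A regressor orthogonal to the design and the residuals leaves the
        likelihood untouched, so its AIC penalty is exactly +2."""
        import statsmodels.api as sm
        from phylospat.regression import _gaussian_aic
        rng = np.random.default_rng(3)
        n = 60
        x = rng.normal(size=n)
        y = 2 * x + rng.normal(size=n)
        X1 = np.column_stack([np.ones(n), x])
        res1 = sm.OLS(y, X1).fit()
        z = rng.normal(size=n)
        # orthogonalize z against the design and the residuals
        basis = np.column_stack([X1, res1.resid])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        res2 = sm.OLS(y, np.column_stack([X1, z])).fit()
        aic1 = _gaussian_aic(res1.llf, 2)
        aic2 = _gaussian_aic(res2.llf, 3)
        assert res2.llf == pytest.approx(res1.llf, abs=1e-8)
        assert aic2 - aic1 == pytest.approx(2.0, abs=1e-7)

    def test_bedrock_enters_as_block_with_granite_reference(self):
        rng = np.random.default_rng(4)
        n = 300
        X = _candidates(rng, n)
        effects = {"granite": 0.0, "rhyolite": 3.0, "quartz sandstone": -2.0}
        y = pd.Series([effects[b] for b in X["bedrock"]]) + rng.normal(size=n)
        fit = ps.stepwise_glm_aic(y, X)
        assert "bedrock" in fit.terms
        assert "bedrock_granite" not in fit.params.index  # reference level
        assert fit.params["bedrock_rhyolite"] == pytest.approx(3.0, abs=0.5)

    def test_column_order_invariance_without_ties(self):
        rng = np.random.default_rng(5)
        X = _candidates(rng, 200)
        y = 4 * X["x2"] - 2 * X["x3"] + rng.normal(size=200)
        f1 = ps.stepwise_glm_aic(y, X)
        f2 = ps.stepwise_glm_aic(y, X[["x3", "bedrock", "x1", "x2"]])
        assert set(f1.terms) == set(f2.terms)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-9)
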