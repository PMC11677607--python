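"""Spatial weights, Moran's I, and ML spatial autoregressive fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import phylospat as ps
from phylospat.spatial import SpatialWeights


def grid_coords(m):
    xs, ys = np.meshgrid(np.arange(m, dtype=float), np.arange(m, dtype=float))
    return pd.DataFrame({"x": xs.ravel(), "y": ys.ravel()},
                        index=[f"s{i}" for i in range(m * m)])


def simulate_lag(rng, W, X, beta, rho, sd=1.0):
    n = W.shape[0]
    eps = rng.normal(scale=sd, size=n)
    return np.linalg.solve(np.eye(n) - rho * W, X @ beta + eps)


class TestKnnWeights:
    def test_grid_interior_neighbours_are_rook_adjacent(self):
        coords = grid_coords(5)
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        idx = 2 * 5 + 2  # centre cell
        neigh = set(np.nonzero(w.W[idx])[0])
        assert neigh == {idx - 5, idx + 5, idx - 1, idx + 1}

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame({"x": rng.random(30), "y": rng.random(30)})
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        np.testing.assert_allclose(w.W.sum(axis=1), 1.0, atol=1e-12)

    def test_collinear_equidistant_tie_rule(self):
        coords = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]})
        w = ps.knn_weights(coords, k=1, metric="euclidean", row_standardize=False)
        assert w.W[0, 1] == 1 and w.W[2, 1] == 1
        assert w.W[1, 0] == 1  # middle's tie broken by site order

    def test_duplicate_coordinates_warn(self):
        coords = pd.DataFrame({"x": [0.0, 0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0, 0.0]})
        with pytest.warns(UserWarning, match="duplicate"):
            ps.knn_weights(coords, k=2, metric="euclidean")

    def test_great_circle_metric_autodetected(self):
        coords = pd.DataFrame({"lon": [114.52, 114.53, 114.60],
                               "lat": [22.50, 22.50, 22.55]})
        w = ps.knn_weights(coords, k=1, row_standardize=False)
        assert w.scheme["metric"] == "great_circle"
        assert w.W[0, 1] == 1  # nearest in km, not degrees

    def test_self_neighbour_rejected(self):
        with pytest.raises(ValueError, match="self"):
            SpatialWeights(ids=("a", "b"), W=np.eye(2))


class TestMoransI:
    def test_iid_mean_close_to_expectation(self):
        rng = np.random.default_rng(1)
        n = 50
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        draws = [ps.morans_i(rng.normal(size=n), w) for _ in range(300)]
        Is = np.array([d.I for d in draws])
        se = np.sqrt(draws[0].variance / len(draws))
        assert abs(Is.mean() - (-1 / (n - 1))) < 3 * se

    def test_checkerboard_negative(self):
        m = 6
        coords = grid_coords(m)
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        x = np.indices((m, m)).sum(axis=0).ravel() % 2 * 2.0 - 1.0
        res = ps.morans_i(x, w)
        assert res.I < 0
        assert res.p_value < 0.01

    def test_autocorrelated_surface_positive(self):
        rng = np.random.default_rng(2)
        coords = grid_coords(10)
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        x = simulate_lag(rng, w.W, np.ones((100, 1)), np.zeros(1), rho=0.8)
        res = ps.morans_i(x, w)
        assert res.I > 0 and res.p_value < 0.01

    def test_constant_vector_rejected(self):
        coords = grid_coords(3)
        w = ps.knn_weights(coords, k=2, metric="euclidean")
        with pytest.raises(ValueError, match="constant"):
            ps.morans_i(np.ones(9), w)


class TestSarLag:
    def _design(self, rng, n):
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        beta = np.array([1.0, 2.0, -1.5])  # intercept, x1, x2
        return X, beta

    def test_rho_zero_matches_ols_within_two_percent(self):
        """No true autocorrelation: slope estimates agree with OLS to 2%.

        The intercept is excluded — it absorbs rho_hat times the mean of the
        lagged response, i.e. the sampling noise of rho itself."""
        rng = np.random.default_rng(0)
        n = 150
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        X, beta = self._design(rng, n)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        y = simulate_lag(rng, w.W, Xd, beta, rho=0.0)
        fit = ps.fit_sar_lag(y, X, w)
        ols = sm.OLS(y, Xd).fit()
        assert abs(fit.rho) < 0.1
        np.testing.assert_allclose(fit.params.to_numpy()[1:], ols.params[1:], rtol=0.02)

    def test_rho_recovery(self):
        rng = np.random.default_rng(1)
        n = 200
        rhos = []
        for _ in range(20):
            coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
            w = ps.knn_weights(coords, k=4, metric="euclidean")
            X, beta = self._design(rng, n)
            Xd = np.column_stack([np.ones(n), X.to_numpy()])
            y = simulate_lag(rng, w.W, Xd, beta, rho=0.6)
            rhos.append(ps.fit_sar_lag(y, X, w).rho)
        assert 0.5 <= np.mean(rhos) <= 0.7

    def test_profile_optimality(self):
        rng = np.random.default_rng(2)
        n = 80
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        X, beta = self._design(rng, n)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        y = simulate_lag(rng, w.W, Xd, beta, rho=0.5)
        fit = ps.fit_sar_lag(y, X, w)
        fit0 = ps.fit_sar_lag(y - 0 * y, X, SpatialWeights(ids=w.ids, W=np.zeros_like(w.W)))
        assert fit.llf >= fit0.llf - 1e-9
        assert fit.rho_interval[0] < fit.rho < fit.rho_interval[1]

    def test_degenerate_weights_equal_ols_exactly(self):
        rng = np.random.default_rng(3)
        n = 50
        X, beta = self._design(rng, n)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        y = Xd @ beta + rng.normal(size=n)
        w0 = SpatialWeights(ids=tuple(range(n)), W=np.zeros((n, n)))
        fit = ps.fit_sar_lag(y, X, w0)
        ols = sm.OLS(y, Xd).fit()
        assert fit.rho == 0.0
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params, atol=1e-9)
        assert fit.llf == pytest.approx(ols.llf, abs=1e-8)

    def test_sar_absorbs_autocorrelation(self):
        """SAR residual Moran's I sits closer to its expectation than OLS's."""
        rng = np.random.default_rng(4)
        n = 150
        gaps_sar, gaps_ols = [], []
        for _ in range(30):
            coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
            w = ps.knn_weights(coords, k=4, metric="euclidean")
            X, beta = self._design(rng, n)
            Xd = np.column_stack([np.ones(n), X.to_numpy()])
            y = simulate_lag(rng, w.W, Xd, beta, rho=0.6)
            fit = ps.fit_sar_lag(y, X, w)
            ols = sm.OLS(y, Xd).fit()
            mi_sar = fit.resid_moran
            mi_ols = ps.morans_i(ols.resid, w)
            gaps_sar.append(abs(mi_sar.I - mi_sar.expected))
            gaps_ols.append(abs(mi_ols.I - mi_ols.expected))
        assert np.mean(gaps_sar) < np.mean(gaps_ols)

    def test_error_model_recovers_positive_lambda(self):
        rng = np.random.default_rng(5)
        n = 200
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        X, beta = self._design(rng, n)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        u = np.linalg.solve(np.eye(n) - 0.6 * w.W, rng.normal(size=n))
        y = Xd @ beta + u
        fit = ps.fit_sar_lag(y, X, w, model="error")
        assert fit.rho > 0.3


class TestPseudoR2:
    def test_null_against_itself_is_zero(self):
        rng = np.random.default_rng(6)
        n = 60
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = SpatialWeights(ids=tuple(range(n)), W=np.zeros((n, n)))
        y = rng.normal(size=n)
        fit = ps.fit_sar_lag(y, pd.DataFrame(index=pd.RangeIndex(n)), w)
        assert ps.pseudo_r2(fit) == pytest.approx(0.0, abs=1e-10)

    def test_approaches_one_as_noise_vanishes(self):
        rng = np.random.default_rng(7)
        n = 100
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = ps.knn_weights(coords, k=4, metric="euclidean")
        X = pd.DataFrame({"x1": rng.normal(size=n)})
        prev = 0.0
        for sd in (1.0, 0.1, 0.001):
            y = 1.0 + 3.0 * X["x1"].to_numpy() + rng.normal(scale=sd, size=n)
            r2 = ps.fit_sar_lag(y, X, w).pseudo_r2
            assert r2 >= prev
            prev = r2
        assert prev > 0.999

    def test_monotone_in_model_loglik(self):
        from phylospat.spatial import _nagelkerke
        vals = [_nagelkerke(-100.0, ll, 50) for ll in (-100, -90, -80, -50)]
        assert vals == sorted(vals)
        assert vals[0] == 0.0

    def test_corr_variant_needs_y(self):
        rng = np.random.default_rng(8)
        n = 40
        w = SpatialWeights(ids=tuple(range(n)), W=np.zeros((n, n)))
        X = pd.DataFrame({"x1": rng.normal(size=n)})
        y = X["x1"].to_numpy() * 2 + rng.normal(size=n)
        fit = ps.fit_sar_lag(y, X, w)
        with pytest.raises(ValueError):
            ps.pseudo_r2(fit, variant="corr")
        assert 0 <= ps.pseudo_r2(fit, y, variant="corr") <= 1
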