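"""Calibration and recovery studies quantifying the toolkit's statistical behaviour.

Each function runs one self-contained simulation study and returns summary
numbers: exactness of the metric implementations against brute-force
reference evaluations, standard-normal calibration of the SES indices under
a neutral null, recovery of assembly regimes and spatial autocorrelation
parameters, selection consistency of the stepwise-AIC search, and the
normalization postconditions.  The acceptance script and the acceptance
test suite both drive these functions.

Every function takes a ``seed``; all randomness derives from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .metrics import faith_pd, mntd, mpd
from .nulls import ses_table
from .preprocess import drop_collinear, hellinger_transform, range_normalize
from .regression import stepwise_glm_aic
from .simulate import (AssemblyScenario, LandscapeScenario, simulate_assembly,
                       simulate_landscape, simulate_yule_tree)
from .spatial import fit_sar_lag, knn_weights, morans_i
from .trees import Phylogeny, cophenetic_matrix

__all__ = [
    "metric_oracle_errors",
    "neutral_ses_calibration",
    "regime_recovery",
    "morans_i_calibration",
    "sar_rho_recovery",
    "sar_vs_ols_at_rho_zero",
    "stepwise_retention",
    "normalization_checks",
]


# ------------------------------------------------------- brute-force oracles
def _reference_path_distance(tree: Phylogeny, i: int, j: int) -> float:
    """Path-sum distance via explicit root paths (no LCA-depth arithmetic)."""
    def root_path(tip_pos):
        node = int(tree.tip_node_index[tip_pos])
        path = []
        while node != 0:
            path.append(node)
            node = int(tree.parent[node])
        return path
    pa, pb = root_path(i), root_path(j)
    shared = set(pa) & set(pb)
    return (sum(tree.blen[v] for v in pa if v not in shared)
            + sum(tree.blen[v] for v in pb if v not in shared))


def _reference_pd(tree: Phylogeny, taxa) -> float:
    """Root-inclusive PD as the union of the selected tips' root paths."""
    edges: set[int] = set()
    labels = list(tree.tip_labels)
    for t in taxa:
        node = int(tree.tip_node_index[labels.index(t)])
        while node != 0:
            edges.add(node)
            node = int(tree.parent[node])
    return sum(tree.blen[v] for v in edges)


def metric_oracle_errors(n_trees: int = 100, max_tips: int = 12, seed: int = 0) -> dict:
    """Max |error| of PD/MPD/MNTD against brute-force enumeration.

    Random pure-birth trees with 3..max_tips tips; on each, every metric is
    compared with an independent reference evaluation (root-path unions for
    PD, explicit pair/nearest enumeration for MPD/MNTD).
    """
    rng = np.random.default_rng(seed)
    err_pd = err_mpd = err_mntd = err_coph = 0.0
    for _ in range(n_trees):
        n = int(rng.integers(3, max_tips + 1))
        tree = simulate_yule_tree(n, seed=int(rng.integers(2 ** 31)))
        D = cophenetic_matrix(tree)
        for i in range(n):
            for j in range(i + 1, n):
                err_coph = max(err_coph, abs(D.values[i, j] - _reference_path_distance(tree, i, j)))
        k = int(rng.integers(2, n + 1))
        taxa = list(rng.choice(list(tree.tip_labels), size=k, replace=False))
        idx = [list(D.labels).index(t) for t in taxa]
        pairs = [D.values[a, b] for u, a in enumerate(idx) for b in idx[u + 1:]]
        nearest = [min(D.values[a, b] for b in idx if b != a) for a in idx]
        err_pd = max(err_pd, abs(faith_pd(tree, taxa) - _reference_pd(tree, taxa)))
        err_mpd = max(err_mpd, abs(mpd(D, taxa) - float(np.mean(pairs))))
        err_mntd = max(err_mntd, abs(mntd(D, taxa) - float(np.mean(nearest))))
    return {"cophenetic": err_coph, "pd": err_pd, "mpd": err_mpd, "mntd": err_mntd,
            "n_trees": n_trees}


# --------------------------------------------------------- SES calibration
def neutral_ses_calibration(
    n_sites: int = 500,
    n_null: int = 999,
    pool_size: int = 128,
    richness: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and sd of NRI/NTI/PDI over neutrally assembled communities.

    Under the taxa-label null the SES of a neutrally drawn community is
    approximately standard normal, so means should sit near 0 and standard
    deviations near 1.
    """
    tree = simulate_yule_tree(pool_size, seed=seed)
    comm = simulate_assembly(tree, AssemblyScenario(mode="neutral", richness=richness,
                                                    n_sites=n_sites, seed=seed + 1))
    tab = ses_table(tree, comm, n_null=n_null, seed=seed + 2)
    out = tab.groupby("metric")["ses"].agg(["mean", "std", "count"])
    return out


def regime_recovery(
    n_sites: int = 200,
    n_null: int = 999,
    pool_size: int = 128,
    richness: int = 12,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean NRI/NTI under filtering and repulsion assembly, with one-sided t.

    Filtering should push both indices positive (clustering), repulsion
    negative (overdispersion); the t statistic tests the mean against zero.
    """
    tree = simulate_yule_tree(pool_size, seed=seed)
    scale = float(np.median(cophenetic_matrix(tree).values))
    rows = []
    for mode, strength in (("filtering", 0.1 * scale), ("repulsion", 1.0)):
        comm = simulate_assembly(tree, AssemblyScenario(
            mode=mode, strength=strength, richness=richness, n_sites=n_sites,
            seed=seed + 10))
        tab = ses_table(tree, comm, indices=("NRI", "NTI"), n_null=n_null, seed=seed + 11)
        for metric, grp in tab.groupby("metric"):
            s = grp["ses"].to_numpy()
            t = s.mean() / (s.std(ddof=1) / np.sqrt(len(s)))
            rows.append({"mode": mode, "metric": metric, "mean_ses": s.mean(),
                         "t_stat": t, "n_sites": len(s)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- spatial
def morans_i_calibration(n: int = 100, n_draws: int = 500, k: int = 4, seed: int = 0) -> dict:
    """Mean Moran's I over iid draws vs the permutation expectation -1/(n-1)."""
    rng = np.random.default_rng(seed)
    coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
    w = knn_weights(coords, k=k, metric="euclidean")
    res = [morans_i(rng.normal(size=n), w) for _ in range(n_draws)]
    Is = np.array([r.I for r in res])
    return {"mean_I": float(Is.mean()), "expected": -1.0 / (n - 1),
            "se_of_mean": float(np.sqrt(res[0].variance / n_draws)), "n": n,
            "n_draws": n_draws}


def sar_rho_recovery(n_reps: int = 100, n: int = 200, rho_true: float = 0.6,
                     seed: int = 0) -> dict:
    """Mean ML estimate of the spatial-lag coefficient over simulated landscapes."""
    rhos = []
    for rep in range(n_reps):
        land = simulate_landscape(LandscapeScenario(n_sites=n, rho_true=rho_true,
                                                    seed=seed + rep))
        dummies = pd.get_dummies(land.env["bedrock"], dtype=float).iloc[:, 1:]
        X = pd.concat([land.X_true, dummies], axis=1)
        rhos.append(fit_sar_lag(land.y, X, land.weights, compute_resid_moran=False).rho)
    rhos = np.asarray(rhos)
    return {"mean_rho": float(rhos.mean()), "sd_rho": float(rhos.std(ddof=1)),
            "rho_true": rho_true, "n_reps": n_reps, "n": n}


def sar_vs_ols_at_rho_zero(n: int = 150, n_reps: int = 20, seed: int = 0) -> dict:
    """With no true autocorrelation the SAR slope estimates should match OLS.

    Returns the mean (over replicates) of the maximum relative discrepancy of
    the predictor coefficients, and the mean |rho| estimate.  The intercept
    is compared separately in the fit itself but excluded here: it absorbs
    rho_hat times the mean of the spatially lagged response, so its finite-
    sample wobble reflects rho's sampling noise, not a slope disagreement.
    """
    rng = np.random.default_rng(seed)
    rel, rho_abs = [], []
    for _ in range(n_reps):
        coords = pd.DataFrame({"x": rng.random(n), "y": rng.random(n)})
        w = knn_weights(coords, k=4, metric="euclidean")
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        Xd = sm.add_constant(X.to_numpy())
        y = Xd @ np.array([1.0, 2.0, -1.5]) + rng.normal(size=n)
        fit = fit_sar_lag(y, X, w, compute_resid_moran=False)
        ols = sm.OLS(y, Xd).fit()
        # slopes only (position 0 is the intercept); relative to the largest
        # slope, since a per-coefficient ratio is ill-posed for betas near 0
        slopes_sar = fit.params.to_numpy()[1:]
        slopes_ols = ols.params[1:]
        rel.append(float(np.max(np.abs(slopes_sar - slopes_ols)) / np.max(np.abs(slopes_ols))))
        rho_abs.append(abs(fit.rho))
    return {"mean_max_rel_beta_diff": float(np.mean(rel)),
            "mean_abs_rho": float(np.mean(rho_abs)), "n_reps": n_reps, "n": n}


# ------------------------------------------------------------- model search
def stepwise_retention(n_seeds: int = 100, n: int = 200, effect_sd: float = 5.0,
                       seed: int = 0) -> dict:
    """Fraction of runs in which the single true predictor is selected.

    One predictor carries an effect of ``effect_sd`` noise standard
    deviations; three noise covariates and a 3-level factor compete with it.
    Also reports how often an all-noise design ends intercept-only.
    """
    rng = np.random.default_rng(seed)
    retained = 0
    intercept_only = 0
    for _ in range(n_seeds):
        X = pd.DataFrame({
            "x1": rng.normal(size=n), "x2": rng.normal(size=n), "x3": rng.normal(size=n),
            "bedrock": rng.choice(["granite", "rhyolite", "quartz sandstone"], size=n),
        })
        y = effect_sd * X["x1"].to_numpy() + rng.normal(size=n)
        if "x1" in stepwise_glm_aic(y, X).terms:
            retained += 1
        y0 = rng.normal(size=n)
        if not stepwise_glm_aic(y0, X).terms:
            intercept_only += 1
    return {"retained": retained, "n_seeds": n_seeds,
            "retention_pct": 100.0 * retained / n_seeds,
            "intercept_only_pct_under_null": 100.0 * intercept_only / n_seeds}


# ----------------------------------------------------------- preprocessing
def normalization_checks(seed: int = 0) -> dict:
    """Postconditions of the three preprocessing operations on random data."""
    rng = np.random.default_rng(seed)
    M = pd.DataFrame(rng.poisson(1.5, size=(60, 40)) + 0.0)
    M.iloc[:, 0] += 1.0
    hel = hellinger_transform(M)
    norm_dev = float(np.abs((hel.values ** 2).sum(axis=1) - 1.0).max())

    x = rng.normal(size=200) * 37 + 5
    once = range_normalize(x)
    idem_dev = float(np.abs(range_normalize(once) - once).max())

    land = simulate_landscape(LandscapeScenario(seed=seed))
    clim = land.env[[c for c in land.env.columns if c.startswith("BIO")]]
    kept, decisions = drop_collinear(clim, threshold=0.95)
    corr = kept.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    return {"hellinger_max_unit_norm_dev": norm_dev,
            "range_normalize_idempotence_dev": idem_dev,
            "max_retained_abs_r": float(corr.max()),
            "n_dropped": len(decisions)}
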