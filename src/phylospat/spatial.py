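"""Spatial weights, Moran's I, and maximum-likelihood SAR regression.

The spatial-lag model is

    y = rho * W y + X beta + eps,     eps ~ N(0, sigma^2 I)

with W a row-standardized spatial weights matrix (k-nearest-neighbour by
default).  Estimation maximises the concentrated log-likelihood over rho,
with log|I - rho W| evaluated from the (possibly complex) eigenvalues of W;
rho is confined to the interval where the determinant stays positive,
(1/lambda_min, 1/lambda_max) on the real eigenvalue range.  A spatial-error
variant (y = X beta + u, u = lambda W u + eps) is available by flag.

Residual spatial autocorrelation is measured by Moran's I with its
randomization-moment normal approximation (expectation -1/(n-1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SpatialWeights",
    "knn_weights",
    "MoranResult",
    "morans_i",
    "SpatialFit",
    "fit_sar_lag",
    "pseudo_r2",
]

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class SpatialWeights:
    """Spatial weights matrix with no self-neighbours.

    ``W[i, j] > 0`` links site i to neighbour j; if ``row_standardized``,
    every row with at least one neighbour sums to 1.
    """

    ids: tuple
    W: np.ndarray
    scheme: dict = field(default_factory=dict)
    row_standardized: bool = True

    def __post_init__(self) -> None:
        W = self.W
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.ids):
            raise ValueError("W must be square and match ids")
        if (np.diag(W) != 0).any():
            raise ValueError("self-neighbours are not allowed (nonzero diagonal)")
        if (W < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(self.W)
        return pd.DataFrame({"i": [self.ids[a] for a in i],
                             "j": [self.ids[b] for b in j],
                             "w": self.W[i, j]})


def _great_circle_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (WGS84 spherical approximation), km."""
    phi = np.radians(lat)[:, None]
    lam = np.radians(lon)[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    a = np.sin(dphi / 2) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def knn_weights(
    coords: pd.DataFrame,
    k: int = 4,
    row_standardize: bool = True,
    metric: str = "auto",
) -> SpatialWeights:
    """k-nearest-neighbour weights from site coordinates.

    ``coords`` needs columns (lon, lat) or (x, y); with ``metric='auto'`` the
    column names decide (lon/lat -> great-circle km, x/y -> Euclidean).
    Distance ties — including exact duplicate coordinates, which trigger a
    warning — are broken by site order.
    """
    cols = {c.lower(): c for c in coords.columns}
    if metric == "auto":
        if "lon" in cols and "lat" in cols:
            metric = "great_circle"
        elif "x" in cols and "y" in cols:
            metric = "euclidean"
        else:
            raise ValueError("cannot auto-detect coordinates: need lon/lat or x/y columns")
    if metric == "great_circle":
        xy = coords[[cols["lon"], cols["lat"]]].to_numpy(dtype=float)
        d = _great_circle_km(xy[:, 0], xy[:, 1])
    elif metric == "euclidean":
        names = [cols.get("x", coords.columns[0]), cols.get("y", coords.columns[1])]
        xy = coords[names].to_numpy(dtype=float)
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.sqrt((diff ** 2).sum(axis=2))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(coords)
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} sites for k={k} neighbours")
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        warnings.warn("duplicate coordinates found; neighbour ties broken by site order")

    W = np.zeros((n, n))
    for i in range(n):
        di = d[i].copy()
        di[i] = np.inf
        order = np.argsort(di, kind="stable")  # stable sort = tie by site order
        W[i, order[:k]] = 1.0
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return SpatialWeights(
        ids=tuple(coords.index),
        W=W,
        scheme={"type": "knn", "k": k, "metric": metric},
        row_standardized=row_standardize,
    )


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float      # -1/(n-1)
    variance: float      # randomization moments
    z: float
    p_value: float       # two-sided normal approximation


def morans_i(x, weights: SpatialWeights) -> MoranResult:
    """Moran's I of a vector on a spatial weights matrix.

    I = (n / S0) * (sum_ij W_ij z_i z_j) / (sum_i z_i^2) with z the centred
    values.  The p-value uses the normal approximation with moments under
    random permutation of the values across sites.
    """
    x = np.asarray(x, dtype=float)
    W = weights.W
    n = len(x)
    if n != W.shape[0]:
        raise ValueError("x and W are not conformable")
    if np.var(x) == 0:
        raise ValueError("Moran's I undefined for a constant vector")
    S0 = W.sum()
    if S0 == 0:
        raise ValueError("weights matrix has no nonzero entries")
    z = x - x.mean()
    I = (n / S0) * (z @ W @ z) / (z @ z)

    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    EI = -1.0 / (n - 1)
    b2 = n * (z ** 4).sum() / (z ** 2).sum() ** 2
    num = (n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
           - b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0))
    den = (n - 1) * (n - 2) * (n - 3) * S0 * S0
    VI = num / den - EI * EI
    zscore = (I - EI) / np.sqrt(VI)
    p = 2 * stats.norm.sf(abs(zscore))
    return MoranResult(float(I), float(EI), float(VI), float(zscore), float(p))


@dataclass
class SpatialFit:
    """ML fit of a spatial autoregressive model."""

    model: str                   # 'lag' or 'error'
    rho: float                   # spatial coefficient (lambda for 'error')
    rho_se: float
    rho_p: float
    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    llf: float
    aic: float                   # 2k - 2 logLik, k = p + rho + sigma^2
    pseudo_r2: float
    resid_moran: MoranResult | None
    rho_interval: tuple[float, float]
    n: int
    llf_null: float              # intercept-only OLS log-likelihood
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def summary_frame(self) -> pd.DataFrame:
        from .regression import significance_stars
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "se": self.bse.values,
            "z": self.zvalues.values,
            "p": self.pvalues.values,
            "stars": [significance_stars(p) for p in self.pvalues.values],
        })


def _ols_llf(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    n = len(y)
    s2 = (e @ e) / n
    llf = -0.5 * n * (np.log(2 * np.pi) + 1 + np.log(s2))
    return llf, beta, s2


def fit_sar_lag(
    y,
    X: pd.DataFrame,
    weights: SpatialWeights,
    model: str = "lag",
    add_intercept: bool = True,
    pseudo_r2_variant: str = "nagelkerke",
    compute_resid_moran: bool = True,
) -> SpatialFit:
    """Maximum-likelihood spatial autoregressive regression.

    ``model='lag'`` fits (I - rho W) y = X beta + eps by concentrating the
    likelihood over rho; ``model='error'`` fits the analogous error model by
    spatially filtering both y and X.  With an all-zero W the fit reduces to
    OLS exactly (rho pinned at 0).

    Coefficient standard errors are conditional on the estimated spatial
    coefficient (sigma^2 (X'X)^-1); the spatial coefficient's own standard
    error comes from the curvature of the profile log-likelihood.
    """
    if model not in ("lag", "error"):
        raise ValueError("model must be 'lag' or 'error'")
    y = np.asarray(y, dtype=float)
    W = weights.W
    n = len(y)
    if X.shape[0] != n or W.shape[0] != n:
        raise ValueError("y, X and W are not conformable")
    Xd = X.astype(float).copy()
    if add_intercept:
        Xd.insert(0, "intercept", 1.0)
    Xmat = Xd.to_numpy()
    names = list(Xd.columns)

    degenerate = not np.any(W)
    if degenerate:
        lam = np.zeros(1)
        lo, hi = -1.0, 1.0
    else:
        lam = np.linalg.eigvals(W)
        re = lam.real
        lam_min, lam_max = re.min(), re.max()
        lo = 1.0 / lam_min if lam_min < 0 else -0.999999
        hi = 1.0 / lam_max if lam_max > 0 else 0.999999
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"empty/invalid rho search interval ({lo}, {hi})")
    eps = 1e-6 * (hi - lo)

    Wy = W @ y
    WX = W @ Xmat

    def logdet(rho: float) -> float:
        return float(np.log(np.abs(1.0 - rho * lam)).sum().real)

    def profile_llf(rho: float) -> float:
        if model == "lag":
            ll, _, _ = _ols_llf(y - rho * Wy, Xmat)
        else:
            ll, _, _ = _ols_llf(y - rho * Wy, Xmat - rho * WX)
        return ll + logdet(rho)

    if degenerate:
        rho_hat = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda r: -profile_llf(r),
            bounds=(lo + eps, hi - eps),
            method="bounded",
            options={"xatol": 1e-9},
        )
        rho_hat = float(res.x)

    if model == "lag":
        ytrans, Xtrans = y - rho_hat * Wy, Xmat
    else:
        ytrans, Xtrans = y - rho_hat * Wy, Xmat - rho_hat * WX
    llf_conc, beta, s2 = _ols_llf(ytrans, Xtrans)
    llf = llf_conc + logdet(rho_hat)

    XtX_inv = np.linalg.inv(Xtrans.T @ Xtrans)
    bse = np.sqrt(np.diag(s2 * XtX_inv))
    zvals = np.divide(beta, bse, out=np.full_like(beta, np.nan), where=bse > 0)
    pvals = 2 * stats.norm.sf(np.abs(zvals))

    if degenerate:
        rho_se, rho_p = 0.0, 1.0
    else:
        h = 1e-5 * max(1.0, abs(rho_hat))
        r_lo = max(lo + eps, rho_hat - h)
        r_hi = min(hi - eps, rho_hat + h)
        d2 = (profile_llf(r_hi) - 2 * profile_llf(rho_hat) + profile_llf(r_lo)) / ((r_hi - rho_hat) * (rho_hat - r_lo))
        rho_se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else float("nan")
        rho_z = rho_hat / rho_se if rho_se and np.isfinite(rho_se) and rho_se > 0 else float("nan")
        rho_p = float(2 * stats.norm.sf(abs(rho_z))) if np.isfinite(rho_z) else float("nan")

    k = len(beta) + 2  # betas + spatial coefficient + sigma^2
    aic = 2.0 * k - 2.0 * llf

    llf0, _, _ = _ols_llf(y, np.ones((n, 1)))

    if model == "lag":
        resid = y - rho_hat * Wy - Xmat @ beta
        fitted = y - resid
    else:
        resid = ytrans - Xtrans @ beta  # innovations after spatial filtering
        fitted = Xmat @ beta

    if pseudo_r2_variant == "nagelkerke":
        pr2 = _nagelkerke(llf0, llf, n)
    elif pseudo_r2_variant == "corr":
        pr2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.var(fitted) > 0 else 0.0
    else:
        raise ValueError("pseudo_r2_variant must be 'nagelkerke' or 'corr'")

    rmoran = None
    if compute_resid_moran and not degenerate and np.var(resid) > 0:
        rmoran = morans_i(resid, weights)

    return SpatialFit(
        model=model,
        rho=rho_hat,
        rho_se=rho_se,
        rho_p=rho_p,
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        zvalues=pd.Series(zvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=float(s2),
        llf=float(llf),
        aic=float(aic),
        pseudo_r2=pr2,
        resid_moran=rmoran,
        rho_interval=(float(lo), float(hi)),
        n=n,
        llf_null=float(llf0),
        fitted=fitted,
        residuals=resid,
    )


def _nagelkerke(llf0: float, llf1: float, n: int) -> float:
    r2 = 1.0 - np.exp((2.0 / n) * (llf0 - llf1))
    if r2 < 0:
        warnings.warn("model log-likelihood below intercept-only null; pseudo-R2 clamped to 0")
        return 0.0
    return float(min(r2, 1.0))


def pseudo_r2(fit: SpatialFit, y=None, variant: str = "nagelkerke") -> float:
    """Fraction of variation explained, as a likelihood-based pseudo-R².

    Nagelkerke form: 1 - exp((2/n)(logL0 - logL1)) against the intercept-only
    null, clamped to [0, 1].  ``variant='corr'`` instead returns the squared
    observed–fitted Pearson correlation (needs ``y``).
    """
    if variant == "nagelkerke":
        return _nagelkerke(fit.llf_null, fit.llf, fit.n)
    if variant == "corr":
        if y is None:
            raise ValueError("variant='corr' needs the observed response y")
        y = np.asarray(y, dtype=float)
        if np.var(fit.fitted) == 0:
            return 0.0
        return float(np.corrcoef(fit.fitted, y)[0, 1] ** 2)
    raise ValueError("variant must be 'nagelkerke' or 'corr'")
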