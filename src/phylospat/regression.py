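"""Non-spatial statistics: Welch contrasts, single-covariate OLS, stepwise-AIC GLM.

The group contrasts compare a diversity response (species richness or an SES
index) between bedrock classes with unequal-variance t-tests.  The stepwise
Gaussian GLM searches predictor subsets by AIC, treating a categorical factor
(bedrock, reference level granite) as a single block of dummy columns that
enters or leaves together.

AIC convention: AIC = 2k - 2 logLik with k counting every estimated
parameter *including* the error variance (the R glm/AIC convention), so the
ModelFit invariant "a parameter with zero likelihood gain costs exactly 2"
holds by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "significance_stars",
    "GroupContrast",
    "welch_t",
    "group_contrasts",
    "ModelFit",
    "ols_r2",
    "stepwise_glm_aic",
]


def significance_stars(p: float) -> str:
    """Figure convention: * p<0.05, ** p<0.01, *** p<0.001, else ''."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupContrast:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float
    stars: str


def welch_t(a, b, group_a: str = "a", group_b: str = "b", pooled: bool = False) -> GroupContrast:
    """Two-sided t-test contrast between two samples.

    Welch's unequal-variance form by default (Welch–Satterthwaite df);
    ``pooled=True`` gives the classical equal-variance test.  The degenerate
    case of two zero-variance samples with equal means reports t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = float(len(a) + len(b) - 2)
            return GroupContrast(group_a, group_b, float(a.mean()), float(b.mean()),
                                 0.0, df, 1.0, "")
        raise ValueError("both groups have zero variance and different means")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    t, p = float(res.statistic), float(res.pvalue)
    df = float(res.df)
    return GroupContrast(group_a, group_b, float(a.mean()), float(b.mean()),
                         t, df, p, significance_stars(p))


def group_contrasts(values: pd.Series, groups: pd.Series, pooled: bool = False) -> pd.DataFrame:
    """All pairwise contrasts of ``values`` between the levels of ``groups``.

    Levels appear in order of first occurrence; pairs with a group of n < 2
    are reported with NaN statistics rather than dropped silently.
    """
    levels = list(pd.unique(groups))
    rows = []
    for ga, gb in combinations(levels, 2):
        va = values[groups == ga].dropna()
        vb = values[groups == gb].dropna()
        if len(va) < 2 or len(vb) < 2:
            rows.append({"group_a": ga, "group_b": gb, "mean_a": va.mean(), "mean_b": vb.mean(),
                         "t_stat": np.nan, "df": np.nan, "p_value": np.nan, "stars": ""})
            continue
        c = welch_t(va, vb, str(ga), str(gb), pooled=pooled)
        rows.append({"group_a": c.group_a, "group_b": c.group_b, "mean_a": c.mean_a,
                     "mean_b": c.mean_b, "t_stat": c.t_stat, "df": c.df,
                     "p_value": c.p_value, "stars": c.stars})
    return pd.DataFrame(rows)


@dataclass
class ModelFit:
    """A fitted Gaussian linear model and its selection metadata."""

    response: str
    terms: list[str]                 # selected model terms (factor = one term)
    params: pd.Series                # coefficient estimates (incl. intercept)
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    aic: float                       # 2k - 2 logLik, k counts sigma^2
    r2: float
    n: int
    selection_log: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "se": self.bse.values,
            "p": self.pvalues.values,
            "stars": [significance_stars(p) for p in self.pvalues.values],
        })


def _gaussian_aic(llf: float, n_coef: int) -> float:
    return 2.0 * (n_coef + 1) - 2.0 * llf  # +1 for the error variance


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    model = sm.OLS(y, X)
    return model.fit()


def ols_r2(y, x, response: str = "y", covariate: str = "x") -> ModelFit:
    """Simple least-squares regression of a response on one covariate.

    Returns slope/intercept, R², and the two-sided p-value of the slope.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0:
        raise ValueError("constant covariate: slope undefined")
    X = pd.DataFrame({"intercept": np.ones_like(x), covariate: x})
    res = _fit_ols(y, X)
    return ModelFit(
        response=response,
        terms=[covariate],
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        aic=_gaussian_aic(float(res.llf), len(res.params)),
        r2=float(res.rsquared),
        n=len(y),
    )


def _design_blocks(X: pd.DataFrame, categorical, reference: dict[str, str]):
    """Map each model term to its design columns (factor -> dummy block)."""
    blocks: dict[str, pd.DataFrame] = {}
    for col in X.columns:
        if col in categorical:
            levels = list(pd.unique(X[col]))
            ref = reference.get(col)
            if ref is not None and ref in levels:
                levels = [ref] + [l for l in levels if l != ref]
            dummies = pd.get_dummies(pd.Categorical(X[col], categories=levels),
                                     prefix=col, dtype=float)
            blocks[col] = dummies.iloc[:, 1:]  # drop reference level
            blocks[col].index = X.index
        else:
            blocks[col] = X[[col]].astype(float)
    return blocks


def _assemble(blocks, terms, n, index) -> pd.DataFrame:
    parts = [pd.DataFrame({"intercept": np.ones(n)}, index=index)]
    parts += [blocks[t] for t in terms]
    return pd.concat(parts, axis=1)


def stepwise_glm_aic(
    y,
    X: pd.DataFrame,
    response: str = "y",
    categorical=("bedrock",),
    reference: dict[str, str] | None = None,
    direction: str = "both",
    start_terms=(),
) -> ModelFit:
    """Stepwise Gaussian GLM (identity link) guided by AIC.

    From the start model (intercept-only by default), each step evaluates
    adding any excluded term and — for ``direction='both'`` — dropping any
    included term, takes the single move with the largest AIC decrease, and
    stops at a local AIC minimum.  Categorical factors move as a block of
    dummy columns (granite is the conventional bedrock reference).  AIC ties
    are broken by declared candidate order and noted in the selection log.

    Perfectly collinear candidates (rank-deficient against the already
    screened design) are excluded up front with a warning.
    """
    if direction not in ("both", "forward"):
        raise ValueError("direction must be 'both' or 'forward'")
    reference = {"bedrock": "granite", **(reference or {})}
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= X.shape[1]:
        raise ValueError("need more observations than candidate predictors")
    categorical = tuple(c for c in categorical if c in X.columns)
    blocks = _design_blocks(X, categorical, reference)

    # screen out perfectly collinear candidate terms
    terms_order = []
    screened = pd.DataFrame({"intercept": np.ones(n)}, index=X.index)
    for t in X.columns:
        trial = pd.concat([screened, blocks[t]], axis=1)
        if np.linalg.matrix_rank(trial.to_numpy()) < trial.shape[1]:
            warnings.warn(f"candidate {t!r} is perfectly collinear with earlier terms; excluded")
            continue
        terms_order.append(t)
        screened = trial

    log: list[str] = []
    current: list[str] = [t for t in start_terms if t in terms_order]

    def aic_of(terms) -> tuple[float, object]:
        design = _assemble(blocks, terms, n, X.index)
        res = _fit_ols(y, design)
        return _gaussian_aic(float(res.llf), len(res.params)), res

    best_aic, best_res = aic_of(current)
    log.append(f"start: terms={current or ['<intercept>']} AIC={best_aic:.4f}")
    while True:
        moves = []  # (aic, order_key, action, term)
        for i, t in enumerate(terms_order):
            if t not in current:
                a, _ = aic_of(current + [t])
                moves.append((a, i, "add", t))
        if direction == "both":
            for i, t in enumerate(terms_order):
                if t in current:
                    a, _ = aic_of([u for u in current if u != t])
                    moves.append((a, i, "drop", t))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))  # declared order breaks AIC ties
        a, _, action, term = moves[0]
        if a >= best_aic - 1e-10:
            break
        near_ties = [m for m in moves[1:] if abs(m[0] - a) < 1e-10]
        if near_ties:
            log.append(f"tie at AIC={a:.4f} broken by declared order in favour of {term!r}")
        current = current + [term] if action == "add" else [u for u in current if u != term]
        best_aic, best_res = aic_of(current)
        log.append(f"{action} {term!r}: AIC={best_aic:.4f}")

    res = best_res
    return ModelFit(
        response=response,
        terms=list(current),
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        llf=float(res.llf),
        aic=best_aic,
        r2=float(res.rsquared) if current else 0.0,
        n=n,
        selection_log=log,
    )
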