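"""Data normalization and collinearity screening for the regression stage.

Three small, order-sensitive steps applied before any model fitting:

* Hellinger transformation of the site x species table,
* (x - min) / (max - min) range normalization of quantitative covariates,
* greedy Pearson screening of the (typically collinear) climate block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "hellinger_transform",
    "range_normalize",
    "drop_collinear",
    "CollinearityDecision",
]


def hellinger_transform(M: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: entry (s, j) -> sqrt(M[s, j] / rowsum_s).

    Every transformed row has unit sum of squares, which makes community
    composition amenable to Euclidean methods.  Sites with zero total
    occurrence are rejected by name (no community to transform).
    """
    X = np.asarray(M, dtype=float)
    if (X < 0).any():
        raise ValueError("community matrix has negative entries")
    rowsum = X.sum(axis=1)
    if (rowsum == 0).any():
        empty = list(np.asarray(M.index)[rowsum == 0])
        raise ValueError(f"zero-sum (empty) sites cannot be Hellinger-transformed: {empty}")
    out = np.sqrt(X / rowsum[:, None])
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def range_normalize(x) -> np.ndarray | pd.Series:
    """Affine rescale to [0, 1]: min -> 0, max -> 1.

    A constant vector has no defined scaling and raises.
    Idempotent on its own output.
    """
    arr = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        raise ValueError("range_normalize undefined for a constant vector (max == min)")
    out = (arr - lo) / (hi - lo)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


@dataclass(frozen=True)
class CollinearityDecision:
    dropped: str
    against: str | None   # retained column it correlated with; None if zero-variance
    r: float | None


def drop_collinear(
    climate: pd.DataFrame,
    threshold: float = 0.95,
    absolute: bool = True,
) -> tuple[pd.DataFrame, list[CollinearityDecision]]:
    """Greedy collinearity screen on the declared column order.

    Scanning columns left to right, a column is dropped if its Pearson
    correlation with any already-retained column exceeds ``threshold``
    (``absolute=True`` compares |r|, also catching strong negative
    collinearity; ``absolute=False`` compares the signed r as literally
    stated).  Zero-variance columns are dropped with a warning before any
    correlation is computed.  Every decision is logged.
    """
    if climate.shape[1] < 2:
        raise ValueError("need at least 2 columns to screen")
    if climate.shape[0] < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    decisions: list[CollinearityDecision] = []
    kept: list[str] = []
    X = climate.astype(float)
    for col in X.columns:
        v = X[col].to_numpy()
        if np.nanstd(v) == 0:
            warnings.warn(f"zero-variance column {col!r} dropped before correlation screen")
            decisions.append(CollinearityDecision(dropped=col, against=None, r=None))
            continue
        offender = None
        for k in kept:
            r = float(np.corrcoef(v, X[k].to_numpy())[0, 1])
            stat = abs(r) if absolute else r
            if stat > threshold:
                offender = (k, r)
                break
        if offender is None:
            kept.append(col)
        else:
            decisions.append(CollinearityDecision(dropped=col, against=offender[0], r=offender[1]))
    retained = X[kept]
    # postcondition: no retained pair exceeds the threshold
    if len(kept) >= 2:
        corr = retained.corr().to_numpy()
        stat = np.abs(corr) if absolute else corr
        np.fill_diagonal(stat, 0.0)
        assert stat.max() <= threshold + 1e-12
    return retained, decisions
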