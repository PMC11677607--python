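"""Randomization null models and standardized effect sizes (PDI, NRI, NTI).

The null model is the taxa-label randomization: each null draw is a uniform
random species set of the same richness drawn from the species pool
(equivalently, a shuffle of the tip labels restricted to the pool).  For each
community metric this yields a null distribution whose mean and standard
deviation standardise the observed value:

    SES = (observed - null_mean) / null_sd

* PDI  =  SES of Faith's PD (positive: more PD than expected at that richness)
* NRI  = -SES of MPD  (positive: phylogenetic clustering, deep structure)
* NTI  = -SES of MNTD (positive: phylogenetic clustering, shallow structure)

When the null distribution is degenerate (null_sd = 0, e.g. the community is
the whole pool) the SES is reported as undefined — flagged, not +/-inf — and
propagates downstream as missing.

Reproducibility contract: a master seed plus the site's index determine the
entire null vector bit-for-bit, independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _m
from .trees import DistanceMatrix, Phylogeny, cophenetic_matrix

__all__ = [
    "SESResult",
    "NULL_MODELS",
    "null_distribution",
    "pdi",
    "nri",
    "nti",
    "classify_structure",
    "ses_table",
]

NULL_MODELS = ("taxa_label",)

_METRIC_OF = {"PDI": "PD", "NRI": "MPD", "NTI": "MNTD"}
_SIGN_OF = {"PDI": 1.0, "NRI": -1.0, "NTI": -1.0}


@dataclass(frozen=True)
class SESResult:
    """A standardized effect size against a randomization null."""

    metric: str           # PDI, NRI or NTI
    observed: float       # observed raw metric (PD, MPD or MNTD)
    null_mean: float
    null_sd: float
    ses: float            # signed per the metric's convention; nan if undefined
    rank_p: float         # fraction of null draws <= observed
    n_null: int
    seed: int | None
    undefined: bool = field(default=False)

    @property
    def raw_metric(self) -> str:
        return _METRIC_OF[self.metric]


def _rng_for_site(seed, site_index: int | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if site_index is None:
        return np.random.default_rng(seed)
    # per-site stream: depends only on (master seed, site index), not on the
    # order in which sites are evaluated
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(site_index,)))


def _draw_subsets(rng: np.random.Generator, pool_size: int, richness: int, n_null: int) -> np.ndarray:
    """(n_null, richness) random subsets of range(pool_size), no replacement."""
    if richness > pool_size:
        raise ValueError(f"richness {richness} exceeds pool size {pool_size}")
    keys = rng.random((n_null, pool_size))
    return np.argpartition(keys, richness - 1, axis=1)[:, :richness]


def _metric_values(metric: str, tree: Phylogeny, d: np.ndarray, communities: np.ndarray) -> np.ndarray:
    if metric == "PD":
        return _m.faith_pd_batch(tree, communities)
    if metric == "MPD":
        return _m.mpd_batch(d, communities)
    if metric == "MNTD":
        return _m.mntd_batch(d, communities)
    raise ValueError(f"unknown metric {metric!r}; expected PD, MPD or MNTD")


def null_distribution(
    metric: str,
    tree: Phylogeny,
    community_taxa,
    n_null: int = 999,
    null_model: str = "taxa_label",
    seed=None,
    pool=None,
    D: DistanceMatrix | None = None,
) -> np.ndarray:
    """Null metric values for ``n_null`` richness-matched random assemblages.

    ``pool`` (default: all tree tips) is the species pool the null draws
    from; ``seed`` may be an int or a numpy Generator.
    """
    if null_model not in NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}; available: {NULL_MODELS}")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = _rng_for_site(seed, None)
    pool_labels = tuple(pool) if pool is not None else tree.tip_labels
    pool_idx = tree.tip_indices(pool_labels)
    richness = len(set(community_taxa))
    d = cophenetic_matrix(tree).values if (D is None and metric != "PD") else (D.values if D is not None else None)
    draws = pool_idx[_draw_subsets(rng, len(pool_idx), richness, n_null)]
    return _metric_values(metric, tree, d, draws)


def _ses(
    index_name: str,
    tree: Phylogeny,
    taxa,
    n_null: int,
    seed,
    site_index: int | None,
    pool,
    D: DistanceMatrix | None,
) -> SESResult:
    raw = _METRIC_OF[index_name]
    sign = _SIGN_OF[index_name]
    rng = _rng_for_site(seed, site_index)
    taxa = sorted(set(taxa))
    idx = tree.tip_indices(taxa)
    if D is None and raw != "PD":
        D = cophenetic_matrix(tree)
    d = None if raw == "PD" else D.values
    if raw == "PD":
        observed = float(_m.faith_pd_batch(tree, idx[None, :])[0])
    else:
        obs_idx = D.indices(taxa)
        observed = float(_metric_values(raw, tree, d, obs_idx[None, :])[0])

    pool_labels = tuple(pool) if pool is not None else tree.tip_labels
    pool_idx = tree.tip_indices(pool_labels)
    draws = pool_idx[_draw_subsets(rng, len(pool_idx), len(idx), n_null)]
    if raw != "PD":
        # map tree tip indices into D's ordering (identical when D comes from
        # cophenetic_matrix, but kept explicit for externally supplied D)
        label_arr = np.asarray(tree.tip_labels)
        draws = np.asarray(D.indices(label_arr[draws.ravel()])).reshape(draws.shape)
    null = _metric_values(raw, tree, d, draws)

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_null > 1 else 0.0
    rank_p = float(np.mean(null <= observed))
    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    if null_sd == 0.0:
        return SESResult(index_name, observed, null_mean, null_sd, float("nan"),
                         rank_p, n_null, seed_out, undefined=True)
    ses = sign * (observed - null_mean) / null_sd
    return SESResult(index_name, observed, null_mean, null_sd, float(ses),
                     rank_p, n_null, seed_out)


def pdi(tree, taxa, n_null: int = 999, seed=None, site_index=None, pool=None, D=None) -> SESResult:
    """Phylogenetic Diversity Index: SES of Faith's PD under the taxa-label null."""
    return _ses("PDI", tree, taxa, n_null, seed, site_index, pool, D)


def nri(tree, taxa, n_null: int = 999, seed=None, site_index=None, pool=None, D=None) -> SESResult:
    """Net Relatedness Index: minus the SES of MPD (positive = clustered)."""
    return _ses("NRI", tree, taxa, n_null, seed, site_index, pool, D)


def nti(tree, taxa, n_null: int = 999, seed=None, site_index=None, pool=None, D=None) -> SESResult:
    """Nearest Taxon Index: minus the SES of MNTD (positive = clustered)."""
    return _ses("NTI", tree, taxa, n_null, seed, site_index, pool, D)


def classify_structure(res: SESResult) -> str:
    """Classify a community as clustered / overdispersed / indeterminate.

    NRI and NTI already carry the sign convention where positive means
    phylogenetic clustering.  PDI has the opposite polarity (less diversity
    than expected = clustering), so its sign is inverted first.  Undefined or
    exactly-zero SES values are indeterminate.
    """
    if res.undefined or not np.isfinite(res.ses) or res.ses == 0.0:
        return "indeterminate"
    s = -res.ses if res.metric == "PDI" else res.ses
    return "clustered" if s > 0 else "overdispersed"


def ses_table(
    tree: Phylogeny,
    community: pd.DataFrame,
    indices=("PDI", "NRI", "NTI"),
    n_null: int = 999,
    seed: int = 0,
    pool=None,
) -> pd.DataFrame:
    """SES results for every site (row) of a site x species occurrence table.

    Rows with richness < 2 yield undefined results.  One row per
    (site, index) in the output, in the CSV layout used by the pipeline.
    """
    D = cophenetic_matrix(tree)
    rows = []
    for i, (site_id, row) in enumerate(community.iterrows()):
        taxa = list(row.index[np.asarray(row.values, dtype=float) > 0])
        for index_name in indices:
            if len(taxa) < 2:
                res = SESResult(index_name, float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), n_null, seed, undefined=True)
            else:
                res = _ses(index_name, tree, taxa, n_null, seed, i, pool, D)
            rows.append({
                "site_id": site_id,
                "metric": index_name,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "ses": res.ses,
                "rank_p": res.rank_p,
                "n_null": res.n_null,
                "seed": seed,
                "undefined": res.undefined,
            })
    return pd.DataFrame(rows)
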