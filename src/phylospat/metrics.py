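"""Raw community phylogenetic diversity metrics: Faith's PD, MPD, MNTD.

All three are presence/absence (unweighted) statistics:

* ``faith_pd`` — total branch length of the subtree spanning a community's
  species.  Root-inclusive by default (the spanning subtree is connected to
  the tree root), matching the common software convention; the crown-only
  variant is available with ``include_root=False``.
* ``mpd`` — mean cophenetic distance over all unordered species pairs.
* ``mntd`` — mean, over species, of the distance to the nearest co-occurring
  species.

``*_batch`` variants evaluate a metric on many communities (rows of a tip
index array) at once; the randomization null models lean on these.
"""

from __future__ import annotations

import numpy as np

from .trees import DistanceMatrix, Phylogeny

__all__ = [
    "UndefinedMetricError",
    "faith_pd",
    "mpd",
    "mntd",
    "faith_pd_batch",
    "mpd_batch",
    "mntd_batch",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given community (e.g. fewer than 2 species)."""


def faith_pd(tree: Phylogeny, taxa, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of a species set.

    Sum of branch lengths of the minimal subtree spanning ``taxa`` — plus the
    path connecting it to the root when ``include_root`` (default).  With all
    tips selected this equals the tree's total branch length.
    """
    idx = tree.tip_indices(taxa)
    if idx.size < 1:
        raise UndefinedMetricError("faith_pd requires at least 1 taxon")
    return float(faith_pd_batch(tree, idx[None, :], include_root=include_root)[0])


def faith_pd_batch(tree: Phylogeny, communities: np.ndarray, include_root: bool = True) -> np.ndarray:
    """PD for each row of tip indices in ``communities`` (shape (m, r)).

    An edge is covered iff at least one selected tip lies below it; the
    root-exclusive variant additionally uncovers the root→MRCA chain, i.e.
    edges below which *all* selected tips lie.
    """
    communities = np.atleast_2d(np.asarray(communities, dtype=np.intp))
    inc = tree.edge_tip_incidence  # (n_nodes, n_tips)
    sel = inc[:, communities]      # (n_nodes, m, r)
    covered = sel.any(axis=2)
    covered[0] = False             # root has no edge above it
    pd = covered.T @ tree.blen
    if not include_root:
        stem = sel.all(axis=2)
        stem[0] = False
        pd -= stem.T @ tree.blen
    return pd


def _check_pairs(idx: np.ndarray) -> None:
    if idx.shape[-1] < 2:
        raise UndefinedMetricError("metric requires at least 2 taxa")


def mpd(D: DistanceMatrix, taxa) -> float:
    """Mean pairwise cophenetic distance over unordered distinct pairs."""
    idx = D.indices(taxa)
    _check_pairs(idx)
    return float(mpd_batch(D.values, idx[None, :])[0])


def mntd(D: DistanceMatrix, taxa) -> float:
    """Mean distance from each species to its nearest co-occurring species."""
    idx = D.indices(taxa)
    _check_pairs(idx)
    return float(mntd_batch(D.values, idx[None, :])[0])


def mpd_batch(d: np.ndarray, communities: np.ndarray) -> np.ndarray:
    """MPD for each row of tip indices (shape (m, r)), r >= 2."""
    communities = np.atleast_2d(np.asarray(communities, dtype=np.intp))
    _check_pairs(communities)
    r = communities.shape[1]
    sub = d[communities[:, :, None], communities[:, None, :]]  # (m, r, r)
    return sub.sum(axis=(1, 2)) / (r * (r - 1))  # off-diagonal mean (diag is 0)


def mntd_batch(d: np.ndarray, communities: np.ndarray) -> np.ndarray:
    """MNTD for each row of tip indices (shape (m, r)), r >= 2."""
    communities = np.atleast_2d(np.asarray(communities, dtype=np.intp))
    _check_pairs(communities)
    sub = d[communities[:, :, None], communities[:, None, :]].copy()
    m, r = communities.shape
    sub[:, np.arange(r), np.arange(r)] = np.inf  # exclude self-distance
    return sub.min(axis=2).mean(axis=1)
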