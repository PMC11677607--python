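"""Rooted phylogenies: newick I/O, traversal arrays, cophenetic distances.

The tree container is a thin, array-backed wrapper around a dendropy tree.
dendropy does the newick parsing/writing; everything downstream (distances,
subtree sums, null models) works on flat numpy arrays indexed in preorder,
which keeps the per-community metric evaluations vectorisable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickError",
    "Phylogeny",
    "DistanceMatrix",
    "parse_newick",
    "read_newick",
    "write_newick",
    "cophenetic_matrix",
]


class NewickError(ValueError):
    """Malformed or invalid newick input (position/offender in the message)."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Cophenetic (patristic) distances between tips, in branch-length units.

    Symmetric, zero diagonal; ``labels`` fixes the row/column order.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, taxa) -> np.ndarray:
        """Integer positions of ``taxa`` in label order; unknown names raise."""
        missing = [t for t in taxa if t not in self._index]
        if missing:
            raise KeyError(f"taxa not in distance matrix: {sorted(missing)}")
        return np.asarray([self._index[t] for t in taxa], dtype=np.intp)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


class Phylogeny:
    """Rooted tree with branch lengths and uniquely labelled tips.

    Nodes are numbered in preorder (root = 0).  ``parent[i]`` is the preorder
    index of node i's parent (-1 for the root), ``blen[i]`` the length of the
    edge above node i (0 for the root), and ``depth[i]`` the root-to-node path
    length.  Tips keep their newick order.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        n = len(nodes)
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(n, -1, dtype=np.intp)
        blen = np.zeros(n)
        is_tip = np.zeros(n, dtype=bool)
        tip_labels: list[str] = []
        tip_node_index: list[int] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = idx[id(nd.parent_node)]
                length = nd.edge.length
                if length is None:
                    label = _node_label(nd)
                    raise NewickError(f"missing branch length on edge above {label!r}")
                if length < 0:
                    raise NewickError(f"negative branch length {length} above {_node_label(nd)!r}")
                blen[i] = float(length)
            if nd.is_leaf():
                is_tip[i] = True
                label = None if nd.taxon is None else nd.taxon.label
                if not label:
                    raise NewickError(f"unlabelled tip at preorder position {i}")
                tip_labels.append(label)
                tip_node_index.append(i)
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({l for l in tip_labels if tip_labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        depth = np.zeros(n)
        for i in range(1, n):  # preorder: parent depth already known
            depth[i] = depth[parent[i]] + blen[i]

        self.parent = parent
        self.blen = blen
        self.depth = depth
        self.is_tip = is_tip
        self.tip_labels: tuple[str, ...] = tuple(tip_labels)
        self.tip_node_index = np.asarray(tip_node_index, dtype=np.intp)
        self._tip_pos = {l: i for i, l in enumerate(tip_labels)}
        self._incidence: np.ndarray | None = None

    # ------------------------------------------------------------------ basics
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def tip_indices(self, taxa) -> np.ndarray:
        """Tip positions (in ``tip_labels`` order) for a set of names."""
        missing = sorted(t for t in taxa if t not in self._tip_pos)
        if missing:
            raise KeyError(f"taxa not found in tree: {missing}")
        return np.asarray([self._tip_pos[t] for t in taxa], dtype=np.intp)

    @property
    def edge_tip_incidence(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): entry [v, t] true iff tip t lies below v.

        Row 0 (root) is all-true.  Computed once and cached; this is the
        workhorse behind fast Faith-PD evaluation over many communities.
        """
        if self._incidence is None:
            inc = np.zeros((self.n_nodes, self.n_tips), dtype=bool)
            inc[self.tip_node_index, np.arange(self.n_tips)] = True
            for v in range(self.n_nodes - 1, 0, -1):  # postorder accumulation
                inc[self.parent[v]] |= inc[v]
            self._incidence = inc
        return self._incidence

    # ---------------------------------------------------------------- newick IO
    def to_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
        )
        return s.strip() + "\n"

    def __repr__(self) -> str:  # pragma: no cover - debugging nicety
        return f"<Phylogeny with {self.n_tips} tips, total length {self.total_branch_length:.4g}>"


def _node_label(nd: dendropy.Node) -> str:
    if nd.taxon is not None and nd.taxon.label:
        return nd.taxon.label
    if nd.label:
        return nd.label
    return "<internal node>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Raises :class:`NewickError` on unbalanced parentheses, duplicate or empty
    tip labels, or missing/negative branch lengths; the message carries the
    parser's position or the offending label.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickError(f"newick parse error: {exc}") from exc
    if dtree.seed_node is None or dtree.seed_node.is_leaf():
        raise NewickError("tree must have at least 2 tips")
    return Phylogeny(dtree)


def read_newick(path) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialise to newick (17 significant digits, lossless round-trip)."""
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def cophenetic_matrix(tree: Phylogeny) -> DistanceMatrix:
    """All pairwise tip-to-tip path-length distances.

    d(i, j) = depth(i) + depth(j) - 2 * depth(lca(i, j)); assembled bottom-up:
    at each internal node, cross-pairs between its children's tip sets have
    that node as their LCA, so each pair is filled exactly once.
    """
    n = tree.n_tips
    d = np.zeros((n, n))
    tipdepth = tree.depth[tree.tip_node_index]
    below: dict[int, list[int]] = {int(v): [i] for i, v in enumerate(tree.tip_node_index)}
    children: dict[int, list[int]] = {}
    for v in range(tree.n_nodes - 1, 0, -1):
        children.setdefault(int(tree.parent[v]), []).append(v)
    for v in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip[v]:
            continue
        groups = [below.pop(c) for c in children.get(v, [])]
        merged: list[int] = []
        for g in groups:
            if merged:
                a = np.asarray(merged, dtype=np.intp)
                b = np.asarray(g, dtype=np.intp)
                block = tipdepth[a][:, None] + tipdepth[b][None, :] - 2.0 * tree.depth[v]
                d[np.ix_(a, b)] = block
                d[np.ix_(b, a)] = block.T
            merged.extend(g)
        below[v] = merged
    return DistanceMatrix(labels=tree.tip_labels, values=d)
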