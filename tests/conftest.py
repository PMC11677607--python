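import numpy as np
import pytest

import phylospat as ps


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the worked example used across metric tests."""
    return ps.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_tip_D(three_tip_tree):
    return ps.cophenetic_matrix(three_tip_tree)


@pytest.fixture
def random_tree_factory():
    def make(n_tips, seed):
        return ps.simulate_yule_tree(n_tips, seed=seed)
    return make


def brute_force_path_distance(tree, i, j):
    """Independent cophenetic oracle: sum branch lengths on the i->j path.

    Walks both root paths and sums lengths of the edges in their symmetric
    difference — no depth/LCA arithmetic shared with the implementation.
    """
    def root_path(tip_pos):
        node = int(tree.tip_node_index[tip_pos])
        path = []
        while node != 0:
            path.append(node)
            node = int(tree.parent[node])
        return path

    pa, pb = root_path(i), root_path(j)
    shared = set(pa) & set(pb)
    return sum(tree.blen[v] for v in pa if v not in shared) + \
        sum(tree.blen[v] for v in pb if v not in shared)


def brute_force_pd(tree, taxa, include_root=True):
    """Independent PD oracle: union of root paths of the selected tips."""
    positions = [list(tree.tip_labels).index(t) for t in taxa]
    edges = set()
    paths = []
    for p in positions:
        node = int(tree.tip_node_index[p])
        path = []
        while node != 0:
            path.append(node)
            node = int(tree.parent[node])
        paths.append(path)
        edges |= set(path)
    if not include_root:
        # remove edges shared by every tip's root path (the root->MRCA chain)
        common = set(paths[0])
        for path in paths[1:]:
            common &= set(path)
        edges -= common
    return sum(tree.blen[v] for v in edges)
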