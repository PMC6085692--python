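"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from cladediv.trees import parse_newick


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random bifurcating Newick with uniform branch lengths (not ultrametric)."""

    def sub(lbls: list[str]) -> str:
        if len(lbls) == 1:
            return f"{lbls[0]}:{rng.uniform(0.1, 2.0):.8f}"
        perm = [lbls[i] for i in rng.permutation(len(lbls))]
        k = int(rng.integers(1, len(perm)))
        return f"({sub(perm[:k])},{sub(perm[k:])}):{rng.uniform(0.1, 2.0):.8f}"

    k = int(rng.integers(1, len(labels)))
    return f"({sub(labels[:k])},{sub(labels[k:])});"


def random_tree(rng: np.random.Generator, n_tips: int):
    labels = [f"t{i}" for i in range(n_tips)]
    return parse_newick(random_newick(rng, labels))


def brute_force_patristic(tree) -> dict[frozenset, float]:
    """Independent patristic oracle: LCA ascent with explicit path sums."""
    parent = {}
    length = {}
    for node in tree.preorder_node_iter():
        parent[node] = node.parent_node
        length[node] = node.edge.length or 0.0
    leaves = list(tree.leaf_node_iter())
    out = {}
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            anc = {}
            node, acc = a, 0.0
            while node is not None:
                anc[node] = acc
                acc += length[node]
                node = parent[node]
            node, acc = b, 0.0
            while node not in anc:
                acc += length[node]
                node = parent[node]
            d = acc + anc[node]
            out[frozenset((a.taxon.label, b.taxon.label))] = d
    return out
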