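"""Phylogenetic tree parsing and patristic distances.

Trees are held as :class:`dendropy.Tree` objects throughout the package.
This module wraps Newick I/O with the validation the downstream analyses
assume (unique tip labels, branch lengths present and non-negative) and
computes patristic distance matrices — the sum of branch lengths along the
unique path between two tips.
"""
from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "NewickError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "tip_labels",
    "node_depths",
    "tree_depth",
    "is_ultrametric",
    "patristic_matrix",
]


class NewickError(ValueError):
    """Raised for malformed or invalid Newick input."""


def parse_newick(text: str, *, require_lengths: bool = True) -> dendropy.Tree:
    """Parse one Newick tree, validating tips and branch lengths.

    Tip labels must be unique; underscores and quoted labels are preserved.
    With ``require_lengths`` every non-root edge must carry a length.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise NewickError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    labels = tip_labels(tree)
    if any(lbl is None or lbl == "" for lbl in labels):
        raise NewickError("unlabeled tip in tree")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge
            continue
        if edge.length is None:
            if require_lengths:
                node = edge.head_node
                where = node.taxon.label if node.taxon else "an internal node"
                raise NewickError(f"missing branch length on the edge above {where}")
            continue
        if edge.length < 0:
            raise NewickError("negative branch length")
    return tree


def read_newick(path: str | Path, **kwargs) -> dendropy.Tree:
    return parse_newick(Path(path).read_text(), **kwargs)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance from the root to every node (root edge length ignored)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tree_depth(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True if all root-to-tip path lengths agree to ``rel_tol`` × depth."""
    depths = node_depths(tree)
    tips = [depths[leaf] for leaf in tree.leaf_node_iter()]
    depth = max(tips)
    if depth == 0.0:
        return True
    return (max(tips) - min(tips)) <= rel_tol * depth


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all tip pairs."""
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("patristic_matrix needs a tree with at least 2 tips")
    labels = [leaf.taxon.label for leaf in leaves]
    pdm = tree.phylogenetic_distance_matrix()
    n = len(leaves)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(tuple(labels), d)
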