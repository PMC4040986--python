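"""Shared utilities over dendropy trees.

Everything downstream (consistency scoring, NJ output handling, 16S
clustering) speaks in terms of leaf-label sets: a bipartition is the pair of
leaf sets induced by removing one edge of the unrooted tree, stored
canonically as the smaller side. Patristic distances are path sums of branch
lengths between leaves.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "parse_newick",
    "read_newick",
    "write_newick",
    "leaf_labels",
    "canonical_split",
    "bipartitions",
    "patristic_matrix",
    "patristic_distance",
    "is_monophyletic",
]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy Tree."""
    return dendropy.Tree.get(data=text, schema="newick")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Sorted labels of all leaves."""
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Canonical representation of a bipartition: the smaller side.

    Size ties are broken by the lexicographically smaller sorted label tuple,
    so either side maps to the same key.
    """
    comp = frozenset(all_leaves - side)
    side = frozenset(side)
    return min((side, comp), key=lambda s: (len(s), tuple(sorted(s))))


def bipartitions(tree: dendropy.Tree) -> list[frozenset]:
    """All splits of the unrooted tree, one per edge, pendant edges included.

    Each split is the canonical (smaller) side as a frozenset of leaf labels.
    A rooted bifurcation at the seed node contributes a single split for its
    two root-adjacent edges, matching the unrooted edge count (2n - 3 for a
    binary tree on n leaves).
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not below or below == all_leaves:
            continue
        splits.add(canonical_split(below, all_leaves))
    return sorted(splits, key=lambda s: (len(s), tuple(sorted(s))))


def _require_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges with missing branch lengths")


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """All-pairs patristic (path-length) distances between leaves.

    Returns the sorted leaf labels and the corresponding symmetric matrix.
    """
    _require_branch_lengths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    labels = sorted(taxa)
    n = len(labels)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return labels, d


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Branch-length sum along the unique leaf-to-leaf path; 0 when a == b."""
    taxa = {lf.taxon.label: lf.taxon for lf in tree.leaf_node_iter()}
    for label in (a, b):
        if label not in taxa:
            raise KeyError(f"leaf {label!r} not in tree")
    if a == b:
        return 0.0
    _require_branch_lengths(tree)
    pdm = tree.phylogenetic_distance_matrix()
    return float(pdm.patristic_distance(taxa[a], taxa[b]))


def is_monophyletic(tree: dendropy.Tree, group) -> bool:
    """True iff some bipartition side equals the group exactly."""
    group = frozenset(group)
    if not group:
        raise ValueError("group must be non-empty")
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not group <= all_leaves:
        raise KeyError(f"group members not in tree: {sorted(group - all_leaves)}")
    if group == all_leaves:
        return True
    return canonical_split(group, all_leaves) in set(bipartitions(tree))
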