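"""Strict and majority-rule consensus of equally optimal trees.

Both consensus trees are assembled from bipartition counts: the strict
consensus keeps exactly the bipartitions present in every input tree; the
majority-rule consensus keeps those in strictly more than the threshold
fraction (default >50%) and annotates each retained clade with its
frequency. Ties at exactly the threshold are excluded.
"""
from __future__ import annotations

from collections import Counter

from ..errors import ValidationError
from .trees import Tree, build_tree_from_clusters

__all__ = ["bipartition_counts", "strict_consensus", "majority_consensus"]


def _common_leaves(trees: list[Tree]) -> frozenset[str]:
    if not trees:
        raise ValidationError("need at least one tree")
    leaves = trees[0].leaf_names()
    for t in trees[1:]:
        if t.leaf_names() != leaves:
            raise ValidationError("consensus requires identical leaf sets")
    return leaves


def bipartition_counts(trees: list[Tree], reference: str | None = None) -> Counter:
    """Occurrence count of every non-trivial bipartition across the trees."""
    leaves = _common_leaves(trees)
    if reference is None:
        reference = min(leaves)
    counts: Counter = Counter()
    for t in trees:
        counts.update(t.bipartitions(reference).keys())
    return counts


def strict_consensus(trees: list[Tree]) -> Tree:
    """Tree containing exactly the bipartitions shared by all input trees."""
    leaves = _common_leaves(trees)
    reference = min(leaves)
    counts = bipartition_counts(trees, reference)
    n = len(trees)
    clusters = {bip: None for bip, c in counts.items() if c == n}
    return build_tree_from_clusters(sorted(leaves), clusters, reference)


def majority_consensus(trees: list[Tree], threshold: float = 0.5) -> Tree:
    """Consensus of bipartitions occurring in > ``threshold`` of the trees.

    Retained clades carry their frequency as ``support`` in [0, 1]. With the
    default 0.5 this is the 50% majority rule; bipartitions at exactly the
    threshold are dropped.
    """
    if not 0.5 <= threshold < 1.0:
        raise ValidationError(f"threshold must be in [0.5, 1), got {threshold}")
    leaves = _common_leaves(trees)
    reference = min(leaves)
    counts = bipartition_counts(trees, reference)
    n = len(trees)
    clusters = {
        bip: c / n for bip, c in counts.items() if c / n > threshold
    }
    return build_tree_from_clusters(sorted(leaves), clusters, reference)
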