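"""Tree topology container with unrooted semantics.

Trees are stored as rooted node structures purely for traversal; all
comparisons (bipartitions, Robinson-Foulds, deduplication) use unrooted
semantics. A bipartition is canonicalised as the frozenset of leaf names on
the side *not* containing a reference leaf (the outgroup when one is
designated, else the lexicographically smallest leaf), so rooted and
unrooted views of the same topology always hash identically.
"""
from __future__ import annotations

import dendropy

from ..errors import ParseError, ValidationError


class TreeNode:
    __slots__ = ("label", "children", "support")

    def __init__(self, label: str | None = None, children=None, support=None):
        self.label = label
        self.children: list[TreeNode] = list(children) if children else []
        self.support: float | None = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()


class Tree:
    """An (un)rooted tree over uniquely labelled leaves; no branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [lf.label for lf in root.leaves()]
        if any(n is None for n in names):
            raise ValidationError("every leaf must be labelled")
        if len(set(names)) != len(names):
            raise ValidationError("leaf labels must be unique")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        text = text.strip()
        if not text:
            raise ParseError("empty newick string")
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ParseError(f"invalid newick: {exc}") from None

        def convert(dnode) -> TreeNode:
            if dnode.is_leaf():
                if dnode.taxon is None:
                    raise ParseError("newick leaf without a label")
                return TreeNode(label=dnode.taxon.label)
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    support = None
            return TreeNode(
                children=[convert(c) for c in dnode.child_nodes()], support=support
            )

        root = convert(dtree.seed_node)
        if root.is_leaf:
            raise ParseError("newick describes a single leaf, not a tree")
        return cls(root)

    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return _quote_label(node.label)
            inner = ",".join(fmt(c) for c in node.children)
            sup = ""
            if include_support and node.support is not None:
                sup = f"{node.support:g}"
            return f"({inner}){sup}"

        return fmt(self.root) + ";"

    # -- queries ----------------------------------------------------------
    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.label for lf in self.root.leaves())

    def bipartitions(self, reference: str | None = None) -> dict[frozenset, float | None]:
        """Non-trivial bipartitions -> support (None if unannotated).

        Each bipartition is the leaf-name frozenset on the side not
        containing the reference leaf.
        """
        all_names = self.leaf_names()
        n = len(all_names)
        if reference is None:
            reference = min(all_names)
        elif reference not in all_names:
            raise ValidationError(f"reference leaf {reference!r} not in tree")
        out: dict[frozenset, float | None] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            side = below if reference not in below else all_names - below
            if 2 <= len(side) <= n - 2:
                out[side] = node.support
            return below

        for child in self.root.children:
            walk(child)
        return out

    def topology_key(self, reference: str | None = None) -> frozenset:
        """Hashable unrooted-topology identity (set of bipartitions)."""
        return frozenset(self.bipartitions(reference).keys())

    def __eq__(self, other) -> bool:
        if not isinstance(other, Tree):
            return NotImplemented
        return (
            self.leaf_names() == other.leaf_names()
            and self.topology_key() == other.topology_key()
        )

    def __hash__(self) -> int:
        return hash((self.leaf_names(), self.topology_key()))


def rf_distance(a: Tree, b: Tree) -> int:
    """Robinson-Foulds distance: bipartitions not shared between two trees."""
    if a.leaf_names() != b.leaf_names():
        raise ValidationError("trees must share an identical leaf set")
    sa = set(a.bipartitions().keys())
    sb = set(b.bipartitions().keys())
    return len(sa ^ sb)


def build_tree_from_clusters(
    taxa,
    clusters: dict[frozenset, float | None],
    reference: str | None = None,
) -> Tree:
    """Assemble a (possibly multifurcating) tree from nested leaf clusters.

    ``clusters`` maps each non-trivial bipartition (side excluding the
    reference leaf) to an optional support value. Clusters must be pairwise
    compatible (nested or disjoint), which holds automatically for strict
    and >50% majority-rule bipartition sets.
    """
    taxa = list(taxa)
    names = set(taxa)
    if reference is None:
        reference = min(names)
    for cl in clusters:
        if not cl <= names or reference in cl:
            raise ValidationError(f"cluster {sorted(cl)} invalid for this taxon set")
    ordered = sorted(clusters, key=len, reverse=True)
    root = TreeNode()
    node_of: dict[frozenset, TreeNode] = {}
    parent_cluster: dict[frozenset, frozenset | None] = {}
    for cl in ordered:
        host: frozenset | None = None
        for other in ordered:
            if other is cl or len(other) < len(cl):
                continue
            if other != cl and (cl & other) and not cl <= other:
                raise ValidationError(
                    f"incompatible clusters {sorted(cl)} / {sorted(other)}"
                )
            if cl < other and (host is None or len(other) < len(host)):
                host = other
        node = TreeNode(support=clusters[cl])
        node_of[cl] = node
        parent_cluster[cl] = host
    for cl in ordered:
        host = parent_cluster[cl]
        (node_of[host] if host is not None else root).children.append(node_of[cl])
    # place each taxon under the smallest cluster containing it
    for name in sorted(names):
        host = None
        for cl in ordered:
            if name in cl and (host is None or len(cl) < len(host)):
                host = cl
        leaf = TreeNode(label=name)
        (node_of[host] if host is not None else root).children.append(leaf)
    # deterministic child order: by smallest descendant name
    def sort_rec(node: TreeNode) -> str:
        if node.is_leaf:
            return node.label
        keys = [sort_rec(c) for c in node.children]
        order = sorted(range(len(keys)), key=keys.__getitem__)
        node.children = [node.children[i] for i in order]
        return min(keys)

    sort_rec(root)
    return Tree(root)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label
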