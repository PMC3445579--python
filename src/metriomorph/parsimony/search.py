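"""Heuristic and exhaustive most-parsimonious-tree search.

The heuristic is seeded random-addition plus SPR swapping with plateau
exploration: each replicate builds a starting tree by stepwise addition of
the taxa in a random order (always choosing the cheapest insertion edge),
then walks the SPR graph, jumping to any strictly shorter neighbour and
otherwise spreading breadth-first across equally short topologies (swapping
on all shortest trees held in memory, up to the saved-trees cap) until no
tree on the plateau has a shorter neighbour. The pool of shortest trees
across replicates is deduplicated by unrooted topology and capped.

Everything is deterministic under a fixed seed; per-replicate streams come
from :class:`numpy.random.SeedSequence` spawning.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ..config import PipelineConfig
from ..errors import DomainError, ValidationError
from .matrix import CharacterMatrix
from .scoring import ScoringKernel, ensemble_indices
from .trees import Tree, TreeNode

__all__ = ["ParsimonyResult", "search", "exhaustive_search", "random_tree"]


# ---------------------------------------------------------------------------
# internal unrooted-tree representation: adjacency dict {node: set(neighbors)};
# node ids < ntax are leaves (the id is the taxon index)


def _initial_triplet(a: int, b: int, c: int, ntax: int):
    hub = ntax
    return {a: {hub}, b: {hub}, c: {hub}, hub: {a, b, c}}, ntax + 1


def _edges(nbr) -> list[tuple[int, int]]:
    return sorted(
        (u, v) for u in nbr for v in nbr[u] if u < v
    )


def _insert_leaf(nbr, leaf: int, edge: tuple[int, int], new_id: int):
    """Subdivide ``edge`` with a new internal node and hang ``leaf`` on it."""
    u, v = edge
    nbr[u].discard(v)
    nbr[v].discard(u)
    nbr[new_id] = {u, v, leaf}
    nbr[u].add(new_id)
    nbr[v].add(new_id)
    nbr[leaf] = {new_id}


def _copy(nbr):
    return {k: set(v) for k, v in nbr.items()}


def _struct(nbr, root_leaf: int):
    """Nested-tuple form rooted on the edge of ``root_leaf`` (binary root)."""

    def sub(v, parent):
        rest = nbr[v] - {parent}
        if not rest:
            return v
        return tuple(sub(w, v) for w in sorted(rest))

    (neighbor,) = nbr[root_leaf]
    return (root_leaf, sub(neighbor, root_leaf))


def _component(nbr, start: int, blocked: int) -> set[int]:
    """Nodes reachable from ``start`` without crossing the edge to ``blocked``."""
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in nbr[u]:
            if u == start and w == blocked:
                continue
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _bipartitions_idx(nbr, ntax: int) -> frozenset:
    """Unrooted topology key: non-trivial splits as sides excluding taxon 0."""
    all_taxa = frozenset(range(ntax))
    splits = set()

    def walk(v, parent) -> frozenset:
        if v < ntax:
            return frozenset([v])
        below = frozenset()
        for w in nbr[v]:
            if w != parent:
                below |= walk(w, v)
        side = below if 0 not in below else all_taxa - below
        if 2 <= len(side) <= ntax - 2:
            splits.add(side)
        return below

    (neighbor,) = nbr[0]
    walk(neighbor, 0)
    return frozenset(splits)


def _spr_moves(nbr, next_id: int):
    """All SPR rearrangements; yields (new_nbr, next_id) copies."""
    for u, v in itertools.chain(_edges(nbr), ((b, a) for a, b in _edges(nbr))):
        # prune the subtree on v's side of edge (u, v)
        work = _copy(nbr)
        work[u].discard(v)
        work[v].discard(u)
        if not work[u]:  # u is a bare leaf; same move covered from the other side
            continue
        spliced = None
        if len(work[u]) == 2:
            x, y = sorted(work[u])
            del work[u]
            work[x].discard(u)
            work[y].discard(u)
            work[x].add(y)
            work[y].add(x)
            spliced = (x, y)
        pruned = _component(work, v, blocked=-1)
        targets = [
            e
            for e in _edges(work)
            if e[0] not in pruned and e[1] not in pruned and e != spliced
        ]
        for a, b in targets:
            out = _copy(work)
            w = next_id
            out[a].discard(b)
            out[b].discard(a)
            out[w] = {a, b, v}
            out[a].add(w)
            out[b].add(w)
            out[v].add(w)
            yield out, next_id + 1


def _spr_plateau_swap(nbr, next_id: int, kernel, root_leaf: int, ntax: int, cap: int):
    """SPR swap with plateau exploration from one starting tree.

    Jumps to any strictly shorter SPR neighbour; at a given length, spreads
    breadth-first over equally short neighbouring topologies (up to ``cap``
    distinct trees) so the walk can cross flat regions of tree space.
    Returns (plateau topologies {key: nbr}, length, hit_cap).
    """
    current_len = kernel.score(_struct(nbr, root_leaf))
    while True:
        start_key = _bipartitions_idx(nbr, ntax)
        plateau = {start_key: (nbr, next_id)}
        queue = [start_key]
        improved = None
        hit_cap = False
        while queue and improved is None:
            key = queue.pop(0)
            q_nbr, q_next = plateau[key]
            for cand, cand_next in _spr_moves(q_nbr, q_next):
                s = kernel.score(_struct(cand, root_leaf))
                if s < current_len:
                    improved = (cand, cand_next, s)
                    break
                if s == current_len:
                    k = _bipartitions_idx(cand, ntax)
                    if k not in plateau:
                        if len(plateau) < cap:
                            plateau[k] = (cand, cand_next)
                            queue.append(k)
                        else:
                            hit_cap = True
        if improved is None:
            return (
                {k: v[0] for k, v in plateau.items()},
                current_len,
                hit_cap,
            )
        nbr, next_id, current_len = improved


def _to_tree(nbr, matrix: CharacterMatrix) -> Tree:
    """Public Tree rooted at the outgroup leaf (or the first taxon)."""
    root_taxon = (
        matrix.taxon_index(matrix.outgroup) if matrix.outgroup is not None else 0
    )

    def conv(v, parent) -> TreeNode:
        if v < matrix.n_taxa:
            return TreeNode(label=matrix.taxa[v])
        return TreeNode(children=[conv(w, v) for w in sorted(nbr[v] - {parent})])

    (neighbor,) = nbr[root_taxon]
    root = TreeNode(
        children=[TreeNode(label=matrix.taxa[root_taxon]), conv(neighbor, root_taxon)]
    )
    return Tree(root)


def _safe_indices(length: int, matrix: CharacterMatrix):
    try:
        return ensemble_indices(length, matrix)
    except DomainError:
        return (None, None, None)


@dataclass
class ParsimonyResult:
    """Outcome of a most-parsimonious-tree search."""

    mpt_set: list[Tree]
    length: int
    ci: float | None
    ri: float | None
    rc: float | None
    bootstrap_support: dict = field(default_factory=dict)
    truncated: bool = False

    @property
    def n_mpts(self) -> int:
        return len(self.mpt_set)


def search(matrix: CharacterMatrix, cfg: PipelineConfig | None = None) -> ParsimonyResult:
    """Random-addition + SPR heuristic search for shortest trees.

    Deterministic under ``cfg.rng_seed``. The returned pool contains every
    distinct unrooted topology found at the best length, up to
    ``cfg.max_saved_trees`` (``truncated`` reports a hit cap).
    """
    cfg = cfg or PipelineConfig()
    ntax = matrix.n_taxa
    if ntax < 4:
        raise ValidationError("search needs at least four taxa")
    kernel = ScoringKernel(matrix)
    streams = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_random_additions)
    best_len: int | None = None
    pool: dict[frozenset, dict] = {}
    truncated = False

    for stream in streams:
        rng = np.random.default_rng(stream)
        order = [int(i) for i in rng.permutation(ntax)]
        nbr, next_id = _initial_triplet(*order[:3], ntax=ntax)
        for leaf in order[3:]:
            best_edge, best_score = None, None
            for edge in _edges(nbr):
                trial = _copy(nbr)
                _insert_leaf(trial, leaf, edge, next_id)
                s = kernel.score(_struct(trial, order[0]))
                if best_score is None or s < best_score:
                    best_edge, best_score = edge, s
            _insert_leaf(nbr, leaf, best_edge, next_id)
            next_id += 1
        root_leaf = order[0]
        plateau, current_len, hit_cap = _spr_plateau_swap(
            nbr, next_id, kernel, root_leaf, ntax, cfg.max_saved_trees
        )
        if best_len is None or current_len < best_len:
            best_len, pool, truncated = current_len, {}, False
        if current_len == best_len:
            for key, tree_nbr in plateau.items():
                if key not in pool:
                    if len(pool) < cfg.max_saved_trees:
                        pool[key] = tree_nbr
                    else:
                        truncated = True
            truncated = truncated or hit_cap

    assert best_len is not None
    trees = [_to_tree(nbr, matrix) for nbr in pool.values()]
    ci, ri, rc = _safe_indices(best_len, matrix)
    return ParsimonyResult(
        mpt_set=trees, length=best_len, ci=ci, ri=ri, rc=rc, truncated=truncated
    )


def _all_topologies(ntax: int):
    """Every unrooted topology over taxa 0..ntax-1 by sequential insertion."""
    if ntax < 3:
        raise ValidationError("need at least three taxa")
    base, next_id = _initial_triplet(0, 1, 2, ntax)
    partial = [(base, next_id)]
    for leaf in range(3, ntax):
        grown = []
        for nbr, nid in partial:
            for edge in _edges(nbr):
                trial = _copy(nbr)
                _insert_leaf(trial, leaf, edge, nid)
                grown.append((trial, nid + 1))
        partial = grown
    return [nbr for nbr, _ in partial]


def exhaustive_search(matrix: CharacterMatrix) -> ParsimonyResult:
    """Exact search by enumerating all unrooted topologies (<= 9 taxa)."""
    ntax = matrix.n_taxa
    if ntax < 4:
        raise ValidationError("exhaustive search needs at least four taxa")
    if ntax > 9:
        raise ValidationError(
            f"exhaustive enumeration of {ntax} taxa is infeasible (max 9)"
        )
    kernel = ScoringKernel(matrix)
    best_len = None
    best: list = []
    for nbr in _all_topologies(ntax):
        s = kernel.score(_struct(nbr, 0))
        if best_len is None or s < best_len:
            best_len, best = s, [nbr]
        elif s == best_len:
            best.append(nbr)
    trees = [_to_tree(nbr, matrix) for nbr in best]
    ci, ri, rc = _safe_indices(best_len, matrix)
    return ParsimonyResult(mpt_set=trees, length=best_len, ci=ci, ri=ri, rc=rc)


def random_tree(labels, rng: np.random.Generator) -> Tree:
    """Uniform-ish random unrooted binary tree by random sequential addition."""
    labels = list(labels)
    ntax = len(labels)
    if ntax < 3:
        raise ValidationError("need at least three leaves")
    order = [int(i) for i in rng.permutation(ntax)]
    nbr, next_id = _initial_triplet(*order[:3], ntax=ntax)
    for leaf in order[3:]:
        edges = _edges(nbr)
        edge = edges[int(rng.integers(len(edges)))]
        _insert_leaf(nbr, leaf, edge, next_id)
        next_id += 1

    def conv(v, parent) -> TreeNode:
        if v < ntax:
            return TreeNode(label=labels[v])
        return TreeNode(children=[conv(w, v) for w in sorted(nbr[v] - {parent})])

    (neighbor,) = nbr[0]
    root = TreeNode(children=[TreeNode(label=labels[0]), conv(neighbor, 0)])
    return Tree(root)
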