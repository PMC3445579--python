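"""Tree-length scoring and homoplasy indices.

Unordered characters cost one step per change between distinct states
(Fitch counting on binary trees, unit-cost Sankoff on multifurcating ones —
the two agree wherever both apply). Ordered characters cost |i - j| per
change (linear-cost Sankoff), implementing transformational sequences.
Missing entries contribute the full state set and can never add steps.

The ensemble indices follow the standard Farris components: per character,
``m`` is the minimum conceivable number of steps on any tree and ``g`` the
number needed on a star tree (the maximum over trees). Then

    CI = sum(m) / L,   RI = (sum(g) - L) / (sum(g) - sum(m)),   RC = CI * RI

for a tree length ``L``.
"""
from __future__ import annotations

import numpy as np

from ..config import round_half_up
from ..errors import DomainError, ValidationError
from .matrix import MISSING, CharacterMatrix
from .trees import Tree, TreeNode

_INF = np.inf

__all__ = [
    "ScoringKernel",
    "tree_length",
    "min_steps",
    "max_steps",
    "ensemble_indices",
    "rescaled_consistency",
]


class ScoringKernel:
    """Pattern-compressed scorer bound to one character matrix.

    Trees are passed as nested tuples: a leaf is its taxon index, an
    internal node a tuple of child structures. The root tuple may have any
    degree >= 2; scoring is invariant to root placement because both step
    costs are metrics.
    """

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        states = matrix.states
        ordered = matrix.ordered_mask
        self.k = int(max(2, states.max() + 1)) if states.size else 2

        def compress(cols: np.ndarray):
            if cols.shape[1] == 0:
                return cols, np.zeros(0, dtype=np.int64)
            patterns, weights = np.unique(cols, axis=1, return_counts=True)
            return patterns, weights

        u_cols, self.w_u = compress(states[:, ~ordered])
        o_cols, self.w_o = compress(states[:, ordered])
        # Fitch bitmasks: bit s set iff state s allowed; missing = all states
        full = (1 << self.k) - 1
        masks = np.where(u_cols == MISSING, full, 1 << u_cols.clip(min=0))
        self.leaf_masks = masks.astype(np.int32)  # (ntax, Cu)
        # Sankoff leaf cost arrays (ntax, C, k): 0 at the observed state,
        # inf elsewhere; all-zero for missing
        self.leaf_costs_u = self._leaf_costs(u_cols)
        self.leaf_costs_o = self._leaf_costs(o_cols)

    def _leaf_costs(self, cols: np.ndarray) -> np.ndarray:
        ntax, c = cols.shape
        costs = np.full((ntax, c, self.k), _INF)
        miss = cols == MISSING
        costs[miss, :] = 0.0
        rows, chars = np.nonzero(~miss)
        costs[rows, chars, cols[rows, chars]] = 0.0
        return costs

    # -- scoring ----------------------------------------------------------
    def score(self, struct) -> int:
        """Minimum total steps of the tree over all characters."""
        total = 0.0
        binary = _is_binary(struct)
        if self.w_u.size:
            if binary:
                counter = [0.0]
                self._fitch(struct, counter)
                total += counter[0]
            else:
                root = self._sankoff(struct, ordered=False)
                total += float(np.dot(root.min(axis=1), self.w_u))
        if self.w_o.size:
            root = self._sankoff(struct, ordered=True)
            total += float(np.dot(root.min(axis=1), self.w_o))
        return int(round(total))

    def _fitch(self, struct, counter) -> np.ndarray:
        if isinstance(struct, (int, np.integer)):
            return self.leaf_masks[struct]
        masks = [self._fitch(c, counter) for c in struct]
        acc = masks[0]
        for m in masks[1:]:
            inter = acc & m
            empty = inter == 0
            counter[0] += float(np.dot(empty, self.w_u))
            acc = np.where(empty, acc | m, inter)
        return acc

    def _sankoff(self, struct, ordered: bool) -> np.ndarray:
        leaf_costs = self.leaf_costs_o if ordered else self.leaf_costs_u
        if isinstance(struct, (int, np.integer)):
            return leaf_costs[struct]
        children = [self._sankoff(c, ordered) for c in struct]
        acc = None
        for cost in children:
            contrib = (
                _linear_contrib(cost) if ordered else _unit_contrib(cost)
            )
            acc = contrib if acc is None else acc + contrib
        return acc


def _unit_contrib(cost: np.ndarray) -> np.ndarray:
    # min over child states j of cost[j] + (1 if j != i else 0)
    best = cost.min(axis=1, keepdims=True)
    return np.minimum(cost, best + 1.0)


def _linear_contrib(cost: np.ndarray) -> np.ndarray:
    # distance transform: min_j cost[j] + |i - j| via two sweeps
    out = cost.copy()
    k = out.shape[1]
    for j in range(1, k):
        np.minimum(out[:, j], out[:, j - 1] + 1.0, out=out[:, j])
    for j in range(k - 2, -1, -1):
        np.minimum(out[:, j], out[:, j + 1] + 1.0, out=out[:, j])
    return out


def _is_binary(struct) -> bool:
    if isinstance(struct, (int, np.integer)):
        return True
    if len(struct) > 2:
        # a degree-3+ node is fine only at the very top for Fitch counting
        # when every deeper node is binary and the cost is metric; keep it
        # simple and exact by requiring strict binarity below the root
        return False
    return all(_is_binary(c) for c in struct)


def tree_to_struct(tree: Tree, matrix: CharacterMatrix):
    """Convert a labelled Tree to the kernel's nested-index structure."""
    leaf_names = tree.leaf_names()
    extra = leaf_names - set(matrix.taxa)
    if extra:
        raise ValidationError(f"tree leaves not in matrix: {sorted(extra)}")

    def conv(node: TreeNode):
        if node.is_leaf:
            return matrix.taxon_index(node.label)
        return tuple(conv(c) for c in node.children)

    return conv(tree.root)


def tree_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Parsimony length of ``tree`` under the matrix's scoring scheme.

    Handles multifurcations directly (Sankoff); characters for taxa absent
    from the tree are simply ignored by restriction of the matrix.
    """
    leaf_names = tree.leaf_names()
    if leaf_names != set(matrix.taxa):
        # score on the restriction of the matrix to the tree's leaves
        keep = [i for i, t in enumerate(matrix.taxa) if t in leaf_names]
        if len(keep) != len(leaf_names):
            raise ValidationError("tree has leaves without matrix rows")
        matrix = CharacterMatrix(
            taxa=[matrix.taxa[i] for i in keep],
            states=matrix.states[keep],
            ordered_mask=matrix.ordered_mask,
            outgroup=None,
        )
    kernel = ScoringKernel(matrix)
    return kernel.score(tree_to_struct(tree, matrix))


# -- per-character Farris components --------------------------------------

def min_steps(column: np.ndarray, ordered: bool = False) -> int:
    """Minimum steps the character needs on any tree (Farris m)."""
    obs = np.asarray(column)
    obs = obs[obs != MISSING]
    if obs.size == 0:
        return 0
    if ordered:
        return int(obs.max() - obs.min())
    return int(len(np.unique(obs)) - 1)


def max_steps(column: np.ndarray, ordered: bool = False) -> int:
    """Steps the character needs on a star tree (Farris g, the maximum)."""
    obs = np.asarray(column)
    obs = obs[obs != MISSING]
    if obs.size == 0:
        return 0
    if ordered:
        # best hub state of the star is any median of the observations
        candidates = range(int(obs.min()), int(obs.max()) + 1)
        return int(min(np.abs(obs - s).sum() for s in candidates))
    _, counts = np.unique(obs, return_counts=True)
    return int(obs.size - counts.max())


def _farris_sums(matrix: CharacterMatrix, include_uninformative: bool):
    total_m = total_g = 0
    for j in range(matrix.n_characters):
        col = matrix.states[:, j]
        ordered = bool(matrix.ordered_mask[j])
        m = min_steps(col, ordered)
        g = max_steps(col, ordered)
        if not include_uninformative and g == m:
            continue
        total_m += m
        total_g += g
    return total_m, total_g


def ensemble_indices(
    length: int, matrix: CharacterMatrix, include_uninformative: bool = True
) -> tuple[float, float, float]:
    """Ensemble (CI, RI, RC) for a tree of the given length, 3-dp rounded.

    ``include_uninformative=False`` drops characters that cannot show
    homoplasy on any tree (g == m), a convention some programs use for CI.
    """
    total_m, total_g = _farris_sums(matrix, include_uninformative)
    if length < total_m:
        raise ValidationError(
            f"length {length} below the character minimum {total_m}"
        )
    if length == 0:
        return (1.0, 1.0, 1.0)
    if total_g == total_m:
        raise DomainError("RI undefined: no character can show homoplasy")
    ci = total_m / length
    ri = (total_g - length) / (total_g - total_m)
    return (
        round_half_up(ci, 3),
        round_half_up(ri, 3),
        round_half_up(ci * ri, 3),
    )


def rescaled_consistency(ci: float, ri: float) -> float:
    """RC from already-computed ensemble CI and RI (RC = CI * RI, 3 dp)."""
    if not (0 < ci <= 1) or not (0 <= ri <= 1):
        raise DomainError(f"CI/RI out of range: {ci}, {ri}")
    return round_half_up(ci * ri, 3)
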