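"""Synthetic data with known ground truth for parameter-recovery tests.

Two generators:

* :func:`gen_mandible` builds a landmark set whose noiseless optimum-gape
  statistics equal the requested angle and prey-depth fraction exactly
  (closed-form construction), then adds isotropic Gaussian landmark noise
  scaled as a fraction of mandible length.
* :func:`gen_matrix` simulates a discrete character matrix on a known
  (random or supplied) unrooted binary tree: each character evolves with a
  Poisson number of substitution events per branch; unordered characters
  jump to a uniformly random different state, ordered characters take a
  +/-1 step clipped to the state range. Missing cells are masked uniformly
  at random.

The simulators' only job is to produce data with a known generating truth
and controllable noise/homoplasy; they make no claim to realistic
morphological character correlation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .gape import GapeMetrics, LandmarkSet
from .parsimony.matrix import MISSING, CharacterMatrix
from .parsimony.search import random_tree
from .parsimony.trees import Tree, TreeNode

__all__ = [
    "MandibleSimSpec",
    "MatrixSimSpec",
    "SimStats",
    "gen_mandible",
    "gen_matrix",
]


@dataclass(frozen=True)
class MandibleSimSpec:
    """Geometry of a simulated mandible in lateral view.

    ``posterior_tooth_offset_fraction`` is d/L: the along-line distance from
    the glenoid to the posterior-most tooth tip as a fraction of mandible
    length. The implied prey-depth fraction is (d/L) * tan(angle).
    """

    mandible_length_cm: float = 60.0
    true_gape_angle_deg: float = 15.0
    posterior_tooth_offset_fraction: float = 0.45
    n_teeth: int = 12
    tooth_span_fraction: float = 0.4
    landmark_noise_sd: float = 0.0  # as a fraction of mandible length
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.true_gape_angle_deg < 90:
            raise ValidationError("gape angle must be in [0, 90) degrees")
        if not 0 < self.posterior_tooth_offset_fraction < 1:
            raise ValidationError("posterior tooth offset fraction must be in (0,1)")
        if self.n_teeth < 2:
            raise ValidationError("need at least two teeth")
        if self.mandible_length_cm <= 0 or self.tooth_span_fraction <= 0:
            raise ValidationError("lengths and spans must be positive")
        if self.landmark_noise_sd < 0:
            raise ValidationError("noise sd must be non-negative")


def gen_mandible(
    spec: MandibleSimSpec, reference_length_cm: float = 60.0
) -> tuple[LandmarkSet, GapeMetrics]:
    """Simulate one mandible; returns (landmarks, true noiseless metrics).

    The glenoid sits at the origin; the tooth line runs parallel to the
    anteroposterior axis at dorsal offset h = d * tan(angle); tooth tips are
    evenly spaced from the posterior-most tip forward. With zero noise,
    ``optimum_gape`` recovers the specified angle and fraction to 1e-9.
    """
    L = spec.mandible_length_cm
    theta = math.radians(spec.true_gape_angle_deg)
    d = spec.posterior_tooth_offset_fraction * L
    h = d * math.tan(theta)
    if h >= L:
        raise ValidationError(
            f"infeasible geometry: implied prey depth {h:.3g} >= mandible length {L}"
        )
    span = spec.tooth_span_fraction * L
    # anterior is +x; glenoid posterior of the tooth row at x=0
    xs = np.linspace(d + span, d, spec.n_teeth)  # anterior -> posterior
    tooth_tips = np.column_stack([xs, np.full(spec.n_teeth, h)])
    glenoid = np.zeros(2)
    retro = np.array([-0.05 * L, 0.0])
    anterior_tip = retro + np.array([L, 0.0])
    rng = np.random.default_rng(spec.seed)
    if spec.landmark_noise_sd > 0:
        sd = spec.landmark_noise_sd * L
        tooth_tips = tooth_tips + rng.normal(0.0, sd, tooth_tips.shape)
        glenoid = glenoid + rng.normal(0.0, sd, 2)
        retro = retro + rng.normal(0.0, sd, 2)
        anterior_tip = anterior_tip + rng.normal(0.0, sd, 2)
    lm = LandmarkSet(
        specimen_id=f"sim_{spec.seed}",
        tooth_tips=tooth_tips,
        glenoid=glenoid,
        dentary_tip_anterior=anterior_tip,
        retroarticular_posterior=retro,
        mandible_length_override=L,
    )
    fraction = h / L
    truth = GapeMetrics(
        specimen_id=lm.specimen_id,
        gape_angle_deg=spec.true_gape_angle_deg,
        prey_depth_cm=h,
        mandible_length_cm=L,
        prey_depth_fraction=fraction,
        standardized_depth_cm=fraction * reference_length_cm,
        reference_length_cm=reference_length_cm,
    )
    return lm, truth


@dataclass(frozen=True)
class MatrixSimSpec:
    """Settings for simulating a character matrix on a known tree."""

    n_taxa: int = 12
    n_characters: int = 240
    states_per_character: int = 3
    rate: float = 0.05  # expected substitution events per branch
    fraction_ordered: float = 40 / 240
    missing_fraction: float = 0.1
    true_tree: Tree | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValidationError("need at least four taxa")
        if not 2 <= self.states_per_character <= 10:
            raise ValidationError("states per character must be in 2..10")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        for name in ("fraction_ordered", "missing_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")


@dataclass
class SimStats:
    """Diagnostics of one matrix simulation."""

    n_branches: int = 0
    n_state_changes: int = 0  # events that actually changed the state
    n_events: int = 0  # Poisson substitution events drawn


def gen_matrix(
    spec: MatrixSimSpec, stats: SimStats | None = None
) -> tuple[CharacterMatrix, Tree]:
    """Simulate (matrix, generating tree); deterministic under spec.seed."""
    rng = np.random.default_rng(spec.seed)
    labels = [f"T{i + 1:02d}" for i in range(spec.n_taxa)]
    if spec.true_tree is not None:
        tree = spec.true_tree
        labels = sorted(tree.leaf_names())
        if len(labels) != spec.n_taxa:
            raise ValidationError("true_tree leaf count disagrees with n_taxa")
    else:
        tree = random_tree(labels, rng)
    k = spec.states_per_character
    n_ordered = int(round(spec.fraction_ordered * spec.n_characters))
    ordered_mask = np.zeros(spec.n_characters, dtype=bool)
    if n_ordered:
        ordered_mask[
            rng.choice(spec.n_characters, size=n_ordered, replace=False)
        ] = True
    states = np.empty((spec.n_taxa, spec.n_characters), dtype=np.int8)
    row_of = {name: i for i, name in enumerate(labels)}
    if stats is None:
        stats = SimStats()

    def evolve(value: int, ordered: bool) -> int:
        n_events = int(rng.poisson(spec.rate))
        stats.n_events += n_events
        for _ in range(n_events):
            if ordered:
                step = int(rng.integers(0, 2)) * 2 - 1  # -1 or +1
                new = min(max(value + step, 0), k - 1)
            else:
                new = int(rng.integers(0, k - 1))
                if new >= value:
                    new += 1  # uniform over the other k-1 states
            if new != value:
                stats.n_state_changes += 1
            value = new
        return value

    for j in range(spec.n_characters):
        ordered = bool(ordered_mask[j])
        root_state = int(rng.integers(0, k))
        stack = [(child, root_state) for child in tree.root.children]
        if j == 0:
            stats.n_branches = _count_branches(tree.root)
        while stack:
            node, parent_state = stack.pop()
            value = evolve(parent_state, ordered)
            if node.is_leaf:
                states[row_of[node.label], j] = value
            else:
                stack.extend((c, value) for c in node.children)
    if spec.missing_fraction > 0:
        mask = rng.random(states.shape) < spec.missing_fraction
        states[mask] = MISSING
    matrix = CharacterMatrix(
        taxa=tuple(labels), states=states, ordered_mask=ordered_mask
    )
    return matrix, tree


def _count_branches(root: TreeNode) -> int:
    total = 0
    stack = list(root.children)
    while stack:
        node = stack.pop()
        total += 1
        stack.extend(node.children)
    return total
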