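"""Optimum-gape geometry from mandible landmarks in lateral view.

The optimum gape is the gape angle at which multiple teeth come into contact
with a prey item — a soft-tissue-free proxy for biomechanically optimal prey
depth that can be measured consistently on fossil mandibles. The
construction is purely planar:

1. fit a straight line across the tips of the dentary teeth;
2. draw the parallel line through the jaw joint (glenoid);
3. the optimum gape angle is the angle subtended at the glenoid by the tip
   of the posterior-most dentary tooth, i.e. ``atan(h / d)`` where *h* is
   the perpendicular distance between the two parallel lines and *d* the
   along-line distance from the glenoid's projection to the posterior-most
   tooth tip's projection.

The perpendicular offset *h* is the optimum prey depth; dividing by mandible
length *L* gives a dimensionless fraction that standardises prey depth
across species of different size (here conventionally re-expressed at a
60 cm mandible).

Coordinate convention: lateral view, anterior +x, dorsal +y; the reported
angle is an unsigned magnitude, so the convention only fixes signs
internally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .errors import DomainError, GeometryError, ValidationError

__all__ = [
    "LandmarkSet",
    "GapeMetrics",
    "ToothLine",
    "fit_tooth_line",
    "optimum_gape",
    "prey_depth_at_length",
]


@dataclass
class LandmarkSet:
    """Labelled 2-D landmarks of one mandible in lateral view (cm).

    ``tooth_tips`` are ordered anterior to posterior. Mandible length is
    either supplied as a measured override (preferred, matching how the
    comparative tables were built) or derived as the chord from the anterior
    dentary tip to the posterior retroarticular tip.
    """

    specimen_id: str
    tooth_tips: np.ndarray  # (n, 2), anterior -> posterior
    glenoid: np.ndarray  # (2,)
    dentary_tip_anterior: np.ndarray | None = None
    retroarticular_posterior: np.ndarray | None = None
    mandible_length_override: float | None = None

    def __post_init__(self) -> None:
        self.tooth_tips = np.asarray(self.tooth_tips, dtype=float)
        self.glenoid = np.asarray(self.glenoid, dtype=float)
        if self.dentary_tip_anterior is not None:
            self.dentary_tip_anterior = np.asarray(self.dentary_tip_anterior, float)
        if self.retroarticular_posterior is not None:
            self.retroarticular_posterior = np.asarray(
                self.retroarticular_posterior, float
            )
        if self.tooth_tips.ndim != 2 or self.tooth_tips.shape[1] != 2:
            raise ValidationError(
                f"{self.specimen_id}: tooth_tips must be an (n, 2) array"
            )
        if len(self.tooth_tips) < 2:
            raise ValidationError(
                f"{self.specimen_id}: at least two dentary tooth tips required"
            )
        pts = [self.tooth_tips, self.glenoid]
        if self.dentary_tip_anterior is not None:
            pts.append(self.dentary_tip_anterior)
        if self.retroarticular_posterior is not None:
            pts.append(self.retroarticular_posterior)
        if not all(np.all(np.isfinite(p)) for p in pts):
            raise ValidationError(f"{self.specimen_id}: non-finite landmark coordinate")
        if self.mandible_length_override is not None and self.mandible_length_override <= 0:
            raise ValidationError(f"{self.specimen_id}: mandible length must be > 0")

    def mandible_length(self) -> float:
        if self.mandible_length_override is not None:
            return float(self.mandible_length_override)
        if self.dentary_tip_anterior is None or self.retroarticular_posterior is None:
            raise ValidationError(
                f"{self.specimen_id}: no mandible length available "
                "(need an override or both mandible-end landmarks)"
            )
        length = float(
            np.linalg.norm(self.dentary_tip_anterior - self.retroarticular_posterior)
        )
        if length <= 0:
            raise ValidationError(f"{self.specimen_id}: zero-length mandible chord")
        return length


@dataclass(frozen=True)
class ToothLine:
    """Fitted tooth-tip line: a point on the line plus a unit direction.

    The direction is oriented so that travelling along it moves from the
    anterior tooth tips toward the posterior ones (positive = posteriorwards).
    """

    point: np.ndarray
    direction: np.ndarray
    rms_residual: float

    def perpendicular_distance(self, p: np.ndarray) -> float:
        d = np.asarray(p, float) - self.point
        return abs(float(d[0] * self.direction[1] - d[1] * self.direction[0]))

    def along(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, float) - self.point, self.direction))


@dataclass(frozen=True)
class GapeMetrics:
    """Optimum-gape summary for one mandible.

    ``gape_angle_deg``, ``prey_depth_cm`` (= perpendicular offset h) and the
    dimensionless ``prey_depth_fraction`` (= h / mandible length) are kept at
    full precision; rounding happens only when rows are formatted for
    reports.
    """

    specimen_id: str
    gape_angle_deg: float
    prey_depth_cm: float
    mandible_length_cm: float
    prey_depth_fraction: float
    standardized_depth_cm: float
    reference_length_cm: float

    def rounded(self, cfg: PipelineConfig) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "gape_angle_deg": cfg.round_angle(self.gape_angle_deg),
            "prey_depth_fraction": cfg.round_fraction(self.prey_depth_fraction),
            "mandible_length_cm": self.mandible_length_cm,
            "prey_depth_cm": cfg.round_depth(self.prey_depth_cm),
            "standardized_depth_cm": cfg.round_depth(self.standardized_depth_cm),
        }


def fit_tooth_line(tooth_tips: np.ndarray, method: str = "tls") -> ToothLine:
    """Fit the straight line across the dentary tooth tips.

    ``method='tls'`` (default) is total least squares — the first principal
    axis of the points, minimising perpendicular residuals, symmetric in
    x/y and rotation invariant. ``method='chord'`` uses only the first and
    last tips.
    """
    pts = np.asarray(tooth_tips, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValidationError("need at least two 2-D tooth tips")
    if np.allclose(pts, pts[0], atol=1e-12):
        raise GeometryError("all tooth tips coincident; no line defined")
    if method == "chord":
        direction = pts[-1] - pts[0]
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise GeometryError("chord endpoints coincide")
        direction = direction / norm
        centroid = 0.5 * (pts[0] + pts[-1])
    elif method == "tls":
        centroid = pts.mean(axis=0)
        centred = pts - centroid
        # principal axis of the 2x2 scatter matrix
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        direction = vt[0]
    else:
        raise ValidationError(f"unknown tooth-line fit method {method!r}")
    # orient anterior -> posterior: last tip must project after the first
    if np.dot(pts[-1] - pts[0], direction) < 0:
        direction = -direction
    normal = np.array([-direction[1], direction[0]])
    residuals = (pts - centroid) @ normal
    rms = float(np.sqrt(np.mean(residuals**2)))
    return ToothLine(point=centroid, direction=direction, rms_residual=rms)


def optimum_gape(lm: LandmarkSet, cfg: PipelineConfig | None = None) -> GapeMetrics:
    """Compute optimum gape angle and prey depth for one mandible.

    Raises :class:`GeometryError` if the posterior-most tooth tip does not
    lie anterior to the glenoid along the tooth line (d <= 0), in which case
    the angle construction is undefined.
    """
    cfg = cfg or PipelineConfig()
    line = fit_tooth_line(lm.tooth_tips, method=cfg.tooth_line_fit)
    h = line.perpendicular_distance(lm.glenoid)
    # direction is anterior->posterior positive; the glenoid sits posterior
    # of the posterior-most tooth tip, so its along-line coordinate exceeds it
    d = line.along(lm.glenoid) - line.along(lm.tooth_tips[-1])
    if d <= 0:
        raise GeometryError(
            f"{lm.specimen_id}: posterior-most tooth tip is not anterior to the "
            f"jaw joint along the tooth line (d = {d:.4g} cm)"
        )
    length = lm.mandible_length()
    angle = math.degrees(math.atan2(h, d))
    fraction = h / length
    return GapeMetrics(
        specimen_id=lm.specimen_id,
        gape_angle_deg=angle,
        prey_depth_cm=h,
        mandible_length_cm=length,
        prey_depth_fraction=fraction,
        standardized_depth_cm=fraction * cfg.reference_mandible_length_cm,
        reference_length_cm=cfg.reference_mandible_length_cm,
    )


def prey_depth_at_length(fraction: float, length_cm: float) -> float:
    """Prey depth (cm) implied by a depth fraction at a given mandible length."""
    if fraction < 0 or fraction >= 1:
        raise DomainError(f"prey-depth fraction must be in [0, 1), got {fraction}")
    if length_cm <= 0:
        raise DomainError(f"mandible length must be positive, got {length_cm}")
    return fraction * length_cm
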