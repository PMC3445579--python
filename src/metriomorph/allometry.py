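"""Body-size estimation: reference-ratio basicranial lengths and a linear
basicranial -> total-length model.

Two steps, mirroring how body lengths of large geosaurines are estimated
from incomplete material:

1. *Reference ratio.* For a specimen known only from a mandible, basicranial
   length is estimated as ``mandible_length x (ref_basicranial / ref_mandible)``
   using a closely related, three-dimensionally preserved reference skull
   with both measurements. This assumes the basicranium and mandible scale
   in the same proportions as in the reference taxon.

2. *Linear total-length model.* Published basicranial -> total body length
   scaling is reconstructed as an ordinary-least-squares straight line
   through printed (basicranial, total length) calibration pairs, which are
   collinear to under a centimetre. Internal unit is cm; metres appear only
   at the reporting boundary (2 decimals).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import reference_data as ref
from .config import round_half_up
from .errors import DomainError, ValidationError

__all__ = [
    "AllometricReference",
    "AllometricModel",
    "default_reference",
    "default_body_length_model",
    "estimate_basicranial",
    "calibrate_body_length_model",
    "predict_total_length",
]


@dataclass(frozen=True)
class AllometricReference:
    """Reference specimen supplying the basicranial:mandible ratio."""

    ref_taxon: str
    ref_mandible_cm: float
    ref_basicranial_cm: float

    def __post_init__(self) -> None:
        if self.ref_mandible_cm <= 0 or self.ref_basicranial_cm <= 0:
            raise ValidationError("reference lengths must be positive")

    @property
    def ratio(self) -> float:
        # recomputed on access so it can never go stale
        return self.ref_basicranial_cm / self.ref_mandible_cm


@dataclass(frozen=True)
class AllometricModel:
    """Straight line total_length_cm = slope * basicranial_cm + intercept."""

    slope: float
    intercept: float
    anchors: tuple[tuple[float, float], ...]
    max_residual_cm: float

    @property
    def anchor_range(self) -> tuple[float, float]:
        xs = [a for a, _ in self.anchors]
        return (min(xs), max(xs))


def default_reference() -> AllometricReference:
    return AllometricReference(
        ref_taxon=ref.REFERENCE_RATIO_TAXON,
        ref_mandible_cm=ref.REFERENCE_MANDIBLE_CM,
        ref_basicranial_cm=ref.REFERENCE_BASICRANIAL_CM,
    )


def default_body_length_model() -> AllometricModel:
    return calibrate_body_length_model(ref.BODY_LENGTH_ANCHORS)


def estimate_basicranial(
    mandible_cm: float, reference: AllometricReference | None = None
) -> float:
    """Basicranial length (cm) from mandible length via the reference ratio.

    Reported to one decimal place, matching the precision of the published
    estimates; the mapping is linear homogeneous (f(c*m) = c*f(m)).
    """
    if mandible_cm <= 0:
        raise DomainError(f"mandible length must be positive, got {mandible_cm}")
    reference = reference or default_reference()
    return round_half_up(mandible_cm * reference.ratio, 1)


def calibrate_body_length_model(
    anchors: list[tuple[float, float]] | tuple[tuple[float, float], ...],
) -> AllometricModel:
    """OLS line through (basicranial cm, total length cm) calibration pairs.

    With exactly two anchors this is exact interpolation. The maximum
    absolute residual over the anchors is always reported as a fit
    diagnostic.
    """
    anchors = tuple((float(a), float(b)) for a, b in anchors)
    if len(anchors) < 2:
        raise ValidationError("need at least two calibration anchors")
    x = np.array([a for a, _ in anchors])
    y = np.array([b for _, b in anchors])
    if len(np.unique(x)) < len(x):
        raise ValidationError("duplicate basicranial values make the fit singular")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValidationError(f"fitted slope must be positive, got {slope:.4g}")
    resid = np.abs(y - (slope * x + intercept))
    return AllometricModel(
        slope=float(slope),
        intercept=float(intercept),
        anchors=anchors,
        max_residual_cm=float(resid.max()),
    )


def predict_total_length(model: AllometricModel, basicranial_cm: float) -> float:
    """Total body length in metres (2 dp) for a basicranial length in cm."""
    if basicranial_cm <= 0:
        raise DomainError(f"basicranial length must be positive, got {basicranial_cm}")
    total_cm = model.slope * basicranial_cm + model.intercept
    return round_half_up(total_cm / 100.0, 2)


def is_extrapolation(model: AllometricModel, basicranial_cm: float) -> bool:
    lo, hi = model.anchor_range
    return not (lo <= basicranial_cm <= hi)
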