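"""Ziphodont dentition metrics: denticle-size classification, crown
compression ratio and denticle densities.

Ziphodont teeth carry carinae made of a keel plus true denticles. The
macro/micro split is a fixed 300 um threshold on all three denticle
dimensions (apicobasal length, height, transverse width): strictly above on
every dimension is macroziphodont; at or below on every dimension is
microziphodont ("do not exceed" is inclusive, so the boundary value itself
is micro). Mixed patterns are reported as indeterminate rather than guessed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .config import round_half_up
from .errors import DomainError, ValidationError

ZIPHODONT_THRESHOLD_UM = 300.0

__all__ = [
    "ZIPHODONT_THRESHOLD_UM",
    "ToothMeasure",
    "classify_ziphodonty",
    "compression_ratio",
    "denticle_density",
]


@dataclass
class ToothMeasure:
    """Measurements of one tooth crown (mm) and its denticles (um).

    ``denticle_counts`` holds raw (count, span_mm, carina, position) tuples
    from which densities are derived; densities are never stored.
    """

    tooth_id: str
    crown_apicobasal_mm: float | None = None
    crown_mesiodistal_basal_mm: float | None = None
    crown_labiolingual_basal_mm: float | None = None
    denticle_length_um: float | None = None
    denticle_height_um: float | None = None
    denticle_width_um: float | None = None
    denticle_counts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "crown_apicobasal_mm",
            "crown_mesiodistal_basal_mm",
            "crown_labiolingual_basal_mm",
            "denticle_length_um",
            "denticle_height_um",
            "denticle_width_um",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{self.tooth_id}: {name} must be > 0, got {v}")

    def denticle_dims(self) -> tuple[float, float, float]:
        dims = (self.denticle_length_um, self.denticle_height_um, self.denticle_width_um)
        if any(d is None for d in dims):
            raise ValidationError(
                f"{self.tooth_id}: all three denticle dimensions required "
                "for ziphodonty classification"
            )
        return dims  # type: ignore[return-value]


def classify_ziphodonty(
    denticle_length_um: float, denticle_height_um: float, denticle_width_um: float
) -> str:
    """Classify a denticle dimension triple (um) against the 300 um threshold.

    Returns ``"macroziphodont"`` when every dimension strictly exceeds
    300 um, ``"microziphodont"`` when none does, ``"indeterminate"``
    otherwise. Monotone: enlarging any dimension never moves the result
    from macro toward micro.
    """
    dims = (denticle_length_um, denticle_height_um, denticle_width_um)
    if any(d is None for d in dims):
        raise ValidationError("all three denticle dimensions are required")
    if any(d <= 0 for d in dims):
        raise ValidationError(f"denticle dimensions must be positive, got {dims}")
    if all(d > ZIPHODONT_THRESHOLD_UM for d in dims):
        return "macroziphodont"
    if all(d <= ZIPHODONT_THRESHOLD_UM for d in dims):
        return "microziphodont"
    return "indeterminate"


def compression_ratio(mesiodistal_mm: float, labiolingual_mm: float) -> float:
    """Basal mesiodistal:labiolingual crown width ratio, to 2 decimals.

    1.0 is a circular cross-section; larger values indicate labiolingual
    (mediolateral) compression.
    """
    if mesiodistal_mm <= 0 or labiolingual_mm <= 0:
        raise DomainError("crown widths must be positive")
    return round_half_up(mesiodistal_mm / labiolingual_mm, 2)


def denticle_density(count: float, span_mm: float) -> int:
    """Denticles per millimetre of carina, rounded to the nearest integer."""
    if count < 1:
        raise DomainError(f"denticle count must be >= 1, got {count}")
    if span_mm <= 0:
        raise DomainError(f"carinal span must be positive, got {span_mm}")
    return int(round_half_up(count / span_mm, 0))
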