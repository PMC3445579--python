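"""Run configuration: seeds, reference lengths, search effort, rounding.

Reported numbers are rounded half-up at the reporting boundary only (angle to
the nearest degree, prey-depth fraction to the nearest 0.01, lengths to two
decimals); all internal arithmetic stays at full precision.
"""
from __future__ import annotations

import decimal
from dataclasses import dataclass, fields
from pathlib import Path

from .errors import FormatError, ValidationError


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as in printed comparative tables.

    Python's built-in ``round`` is banker's rounding (13.125 -> 13.12); the
    printed tables round halves up (13.125 -> 13.13).
    """
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(value))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass
class PipelineConfig:
    """Settings shared by every stage of the pipeline.

    Parameters
    ----------
    rng_seed
        Single integer seeding every stochastic operation; per-replicate
        streams are derived from it with :class:`numpy.random.SeedSequence`.
    reference_mandible_length_cm
        Mandible length to which prey depths are standardised for
        cross-species comparison (default 60 cm).
    ordered_characters
        1-based indices of characters scored with linear (ordered) costs.
    """

    rng_seed: int = 0
    reference_mandible_length_cm: float = 60.0
    ordered_characters: tuple[int, ...] = ()
    n_random_additions: int = 8
    max_saved_trees: int = 1000
    n_bootstrap_replicates: int = 100
    bootstrap_n_random_additions: int = 2
    angle_decimals: int = 0
    fraction_decimals: int = 2
    depth_decimals: int = 2
    tooth_line_fit: str = "tls"  # "tls" or "chord" (endpoints only)

    def __post_init__(self) -> None:
        if self.reference_mandible_length_cm <= 0:
            raise ValidationError("reference mandible length must be positive")
        if self.tooth_line_fit not in ("tls", "chord"):
            raise ValidationError(
                f"tooth_line_fit must be 'tls' or 'chord', got {self.tooth_line_fit!r}"
            )
        self.ordered_characters = tuple(int(i) for i in self.ordered_characters)
        if any(i < 1 for i in self.ordered_characters):
            raise ValidationError("ordered character indices are 1-based (>= 1)")

    def validate_ordered_indices(self, n_characters: int) -> None:
        bad = [i for i in self.ordered_characters if i > n_characters]
        if bad:
            raise ValidationError(
                f"ordered character indices {bad} exceed n_characters={n_characters}"
            )

    def round_angle(self, deg: float) -> float:
        return round_half_up(deg, self.angle_decimals)

    def round_fraction(self, frac: float) -> float:
        return round_half_up(frac, self.fraction_decimals)

    def round_depth(self, cm: float) -> float:
        return round_half_up(cm, self.depth_decimals)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_INT_KEYS = {
    "rng_seed",
    "n_random_additions",
    "max_saved_trees",
    "n_bootstrap_replicates",
    "bootstrap_n_random_additions",
    "angle_decimals",
    "fraction_decimals",
    "depth_decimals",
}
_FLOAT_KEYS = {"reference_mandible_length_cm"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a plain ``key = value`` config file; '#' starts a comment."""
    values: dict = {}
    known = {f.name for f in fields(PipelineConfig)}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in known:
            raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _INT_KEYS:
            values[key] = int(val)
        elif key in _FLOAT_KEYS:
            values[key] = float(val)
        elif key == "ordered_characters":
            values[key] = tuple(int(t) for t in val.replace(",", " ").split()) if val else ()
        else:
            values[key] = val
    return PipelineConfig(**values)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    lines = []
    for key, val in cfg.as_dict().items():
        if key == "ordered_characters":
            val = " ".join(str(i) for i in val)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")
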