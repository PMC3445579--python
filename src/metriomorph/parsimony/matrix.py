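"""Discrete morphological character matrix: taxa x characters over {0..9}
with missing data, per-character ordered flags and an optional outgroup."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ValidationError

MISSING = -1  # internal code; both '?' and '-' map here


@dataclass
class CharacterMatrix:
    """Taxa x characters state table.

    ``states`` is an int8 array with values 0..9 or ``MISSING`` (-1).
    ``ordered_mask`` marks characters scored with linear |i - j| costs
    (transformational sequences); the rest are unordered (unit cost, Fitch).
    """

    taxa: tuple[str, ...]
    states: np.ndarray
    ordered_mask: np.ndarray | None = None
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("taxon labels must be unique")
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2:
            raise ValidationError("states must be a 2-D array")
        if self.states.shape[0] != len(self.taxa):
            raise ValidationError(
                f"{self.states.shape[0]} state rows for {len(self.taxa)} taxa"
            )
        if self.states.size and (self.states.max() > 9 or self.states.min() < MISSING):
            raise ValidationError("states must lie in 0..9 or be missing (-1)")
        if self.ordered_mask is None:
            self.ordered_mask = np.zeros(self.n_characters, dtype=bool)
        else:
            self.ordered_mask = np.asarray(self.ordered_mask, dtype=bool)
            if self.ordered_mask.shape != (self.n_characters,):
                raise ValidationError(
                    "ordered_mask length must equal the number of characters"
                )
        if self.outgroup is not None and self.outgroup not in self.taxa:
            raise ValidationError(f"outgroup {self.outgroup!r} not among the taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return self.states.shape[1]

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise ValidationError(f"taxon {name!r} not in matrix") from None

    def set_ordered_from_indices(self, indices_1based) -> None:
        """Flag characters ordered from 1-based indices (as printed lists)."""
        mask = np.zeros(self.n_characters, dtype=bool)
        for i in indices_1based:
            if not 1 <= i <= self.n_characters:
                raise ValidationError(
                    f"ordered character index {i} outside 1..{self.n_characters}"
                )
            mask[i - 1] = True
        self.ordered_mask = mask

    def resample_characters(self, indices) -> "CharacterMatrix":
        """New matrix from the given column indices (bootstrap resampling)."""
        idx = np.asarray(indices, dtype=int)
        return CharacterMatrix(
            taxa=self.taxa,
            states=self.states[:, idx].copy(),
            ordered_mask=self.ordered_mask[idx].copy(),
            outgroup=self.outgroup,
        )

    def missing_mask(self) -> np.ndarray:
        return self.states == MISSING
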