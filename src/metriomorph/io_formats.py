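"""Readers and writers for every external representation the pipeline uses:
landmark CSV files, NEXUS / TNT character matrices, Newick trees and TSV
reports.

Conventions
-----------
* Landmark CSV columns: ``specimen_id, taxon, label, x, y`` with an optional
  ``mandible_length_cm`` column (constant within a specimen). Labels come
  from the controlled vocabulary ``glenoid``, ``dentary_tip_anterior``,
  ``retroarticular_posterior`` and ``tooth_tip_NN`` (numbered anterior to
  posterior).
* Character matrices: NEXUS DATA/CHARACTERS blocks (parsed with dendropy)
  or the TNT ``xread`` dialect (parsed here). States are 0..9; both ``?``
  and ``-`` are read as missing; polymorphic codings like ``(01)`` or
  ``[01]`` are accepted but treated as missing, with a warning.
* Trees: Newick with unrooted semantics, one tree per line, no branch
  lengths required.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError
from .gape import LandmarkSet
from .parsimony.matrix import MISSING, CharacterMatrix
from .parsimony.trees import Tree

__all__ = [
    "SpecimenRecord",
    "read_landmark_table",
    "write_landmark_table",
    "read_character_matrix",
    "read_newick",
    "read_newick_list",
    "write_newick",
]

_FIXED_LABELS = {"glenoid", "dentary_tip_anterior", "retroarticular_posterior"}
_TOOTH_RE = re.compile(r"^tooth_tip_(\d{2,})$")


@dataclass
class SpecimenRecord:
    """One specimen: identity, scalar measurements, optional landmarks."""

    specimen_id: str
    taxon: str = ""
    mandible_length_cm: float | None = None
    basicranial_length_cm: float | None = None
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValidationError("specimen_id must be non-empty")
        for name in ("mandible_length_cm", "basicranial_length_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{self.specimen_id}: {name} must be > 0")


# ---------------------------------------------------------------------------
# landmark CSV


def read_landmark_table(path: str | Path) -> list[SpecimenRecord]:
    """Parse a landmark CSV into one SpecimenRecord per specimen.

    Every specimen must provide a glenoid and at least two tooth tips; row
    order is preserved within a specimen and tooth tips are sorted by their
    anterior-to-posterior number.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"specimen_id", "taxon", "label", "x", "y"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path}: missing columns {sorted(missing_cols)}")
    records: list[SpecimenRecord] = []
    for specimen_id, group in df.groupby("specimen_id", sort=False):
        fixed: dict[str, np.ndarray] = {}
        teeth: list[tuple[int, np.ndarray]] = []
        mandible_length = None
        taxon = str(group["taxon"].iloc[0])
        for idx, row in group.iterrows():
            lineno = idx + 2  # header is line 1
            label = row["label"].strip()
            try:
                xy = np.array([float(row["x"]), float(row["y"])])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric coordinate "
                    f"({row['x']!r}, {row['y']!r})"
                ) from None
            m = _TOOTH_RE.match(label)
            if m:
                teeth.append((int(m.group(1)), xy))
            elif label in _FIXED_LABELS:
                if label in fixed:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate {label!r} for {specimen_id}"
                    )
                fixed[label] = xy
            else:
                raise FormatError(f"{path}:{lineno}: unknown landmark label {label!r}")
            if "mandible_length_cm" in group.columns:
                raw = str(row["mandible_length_cm"]).strip()
                if raw:
                    try:
                        mandible_length = float(raw)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{lineno}: non-numeric mandible length {raw!r}"
                        ) from None
        if "glenoid" not in fixed:
            raise ValidationError(f"{specimen_id}: mandatory landmark 'glenoid' missing")
        if len(teeth) < 2:
            raise ValidationError(
                f"{specimen_id}: at least two tooth_tip landmarks required"
            )
        teeth.sort(key=lambda t: t[0])
        lm = LandmarkSet(
            specimen_id=str(specimen_id),
            tooth_tips=np.array([xy for _, xy in teeth]),
            glenoid=fixed["glenoid"],
            dentary_tip_anterior=fixed.get("dentary_tip_anterior"),
            retroarticular_posterior=fixed.get("retroarticular_posterior"),
            mandible_length_override=mandible_length,
        )
        records.append(
            SpecimenRecord(
                specimen_id=str(specimen_id),
                taxon=taxon,
                mandible_length_cm=mandible_length,
                landmarks=lm,
            )
        )
    return records


def write_landmark_table(records: list[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        lm = rec.landmarks
        if lm is None:
            raise ValidationError(f"{rec.specimen_id}: no landmarks to write")

        def add(label, xy):
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "taxon": rec.taxon,
                    "label": label,
                    "x": repr(float(xy[0])),
                    "y": repr(float(xy[1])),
                    "mandible_length_cm": (
                        "" if rec.mandible_length_cm is None else rec.mandible_length_cm
                    ),
                }
            )

        add("glenoid", lm.glenoid)
        if lm.dentary_tip_anterior is not None:
            add("dentary_tip_anterior", lm.dentary_tip_anterior)
        if lm.retroarticular_posterior is not None:
            add("retroarticular_posterior", lm.retroarticular_posterior)
        for i, xy in enumerate(lm.tooth_tips, start=1):
            add(f"tooth_tip_{i:02d}", xy)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# character matrices

_POLY_RE = re.compile(r"[([{][^)\]}]*[)\]}]")


def read_character_matrix(
    path: str | Path,
    dialect: str = "nexus",
    ordered_indices=None,
    outgroup: str | None = None,
) -> CharacterMatrix:
    """Read a discrete character matrix in NEXUS or TNT xread format."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"matrix file not found: {path}")
    if dialect == "nexus":
        taxa, rows = _parse_nexus(path)
    elif dialect == "tnt":
        taxa, rows = _parse_tnt(path)
    else:
        raise ValidationError(f"unknown matrix dialect {dialect!r}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise FormatError(f"{path}: rows of unequal length {sorted(lengths)}")
    if len(set(taxa)) != len(taxa):
        raise FormatError(f"{path}: duplicate taxon labels")
    states = np.array(rows, dtype=np.int8)
    matrix = CharacterMatrix(taxa=tuple(taxa), states=states, outgroup=outgroup)
    if ordered_indices is not None:
        matrix.set_ordered_from_indices(ordered_indices)
    return matrix


def _decode_symbol(sym: str, taxon: str, char_index: int, where: str) -> int:
    if sym in ("?", "-"):
        return MISSING
    if sym.isdigit():
        return int(sym)
    raise FormatError(
        f"{where}: state symbol {sym!r} outside 0-9/?/- "
        f"(taxon {taxon!r}, character {char_index + 1})"
    )


def _expand_row(raw: str, taxon: str, where: str) -> list[int]:
    # polymorphic codings (01), [01], {01} -> missing, with a warning
    if _POLY_RE.search(raw):
        warnings.warn(
            f"{where}: polymorphic coding(s) for {taxon!r} treated as missing",
            stacklevel=3,
        )
        raw = _POLY_RE.sub("?", raw)
    return [_decode_symbol(s, taxon, i, where) for i, s in enumerate(raw)]


def _parse_nexus(path: Path):
    import dendropy

    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:
        raise FormatError(f"{path}: NEXUS parse failed: {exc}") from None
    taxa, rows = [], []
    for taxon in dm.taxon_namespace:
        seq = dm[taxon]
        symbols = []
        for cell in seq:
            sym = str(cell)
            if len(sym) > 1:  # dendropy renders polymorphisms as multi-char
                sym = f"({sym})"
            symbols.append(sym)
        taxa.append(taxon.label)
        rows.append(_expand_row("".join(symbols), taxon.label, str(path)))
    if not rows:
        raise FormatError(f"{path}: no character data found")
    return taxa, rows


def _parse_tnt(path: Path):
    text = path.read_text()
    m = re.search(r"xread\b", text, flags=re.IGNORECASE)
    if not m:
        raise FormatError(f"{path}: no 'xread' block found")
    body = text[m.end():]
    body = re.sub(r"'[^']*'", " ", body)  # strip quoted title
    if ";" in body:
        body = body[: body.index(";")]
    tokens = body.split()
    if len(tokens) < 2:
        raise FormatError(f"{path}: xread header must give nchar and ntax")
    try:
        nchar, ntax = int(tokens[0]), int(tokens[1])
    except ValueError:
        raise FormatError(f"{path}: bad xread dimensions {tokens[:2]}") from None
    entries = tokens[2:]
    if len(entries) != 2 * ntax:
        raise FormatError(
            f"{path}: expected {ntax} taxon/row pairs, found {len(entries) // 2}"
        )
    taxa, rows = [], []
    for i in range(ntax):
        taxon = entries[2 * i].replace("_", " ")
        row = _expand_row(entries[2 * i + 1], taxon, str(path))
        if len(row) != nchar:
            raise FormatError(
                f"{path}: taxon {taxon!r} has {len(row)} states, declared {nchar}"
            )
        taxa.append(taxon)
        rows.append(row)
    return taxa, rows


# ---------------------------------------------------------------------------
# trees


def read_newick_list(path: str | Path) -> list[Tree]:
    """All trees in a Newick file, one per line."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"tree file not found: {path}")
    trees = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(Tree.from_newick(line))
        except ParseError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if not trees:
        raise ParseError(f"{path}: no trees found")
    return trees


def read_newick(path: str | Path) -> Tree:
    """The first (usually only) tree in a Newick file."""
    return read_newick_list(path)[0]


def write_newick(trees, path: str | Path, include_support: bool = False) -> None:
    if isinstance(trees, Tree):
        trees = [trees]
    Path(path).write_text(
        "\n".join(t.to_newick(include_support=include_support) for t in trees) + "\n"
    )
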