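"""Published measurement inputs used by the worked examples and the pipeline.

These are printed specimen measurements (gape angles and prey-depth
fractions, maximum mandible lengths, allometric calibration anchors, tooth
and denticle dimensions) for Late Jurassic metriorhynchid crocodylomorphs.
They are inputs to the toolkit, not outputs: every derived column is
recomputed from them at run time.
"""
from __future__ import annotations

# (taxon, specimen, optimum gape angle deg, prey-depth fraction of mandible
#  length, maximum known mandible length cm) for the seven macrophagy
# comparison species.
GAPE_TABLE_ROWS: tuple[tuple[str, str, float, float, float], ...] = (
    ("Metriorhynchus superciliosus", "NHMUK PV R3016", 11.0, 0.08, 88.0),
    ("'Metriorhynchus' brachyrhynchus", "NHMUK PV R3804", 10.0, 0.07, 82.3),
    ("Mr Leeds' specimen", "GLAHM V972", 15.0, 0.13, 67.0),
    ("Geosaurus giganteus", "NHMUK PV OR37020", 16.0, 0.13, 52.0),
    ("Dakosaurus maximus", "SMNS 82043", 19.0, 0.15, 87.5),
    ("Dakosaurus andiniensis", "(Gasparini et al.)", 23.0, 0.19, 80.0),
    ("Plesiosuchus manselii", "NHMUK PV R1089", 24.0, 0.21, 132.2),
)

# Reference specimen for the basicranial/mandible ratio method:
# 'Metriorhynchus' brachyrhynchus NHMUK PV R3804, the most three-dimensionally
# preserved skull+mandible available.
REFERENCE_RATIO_TAXON = "'Metriorhynchus' brachyrhynchus"
REFERENCE_MANDIBLE_CM = 80.9
REFERENCE_BASICRANIAL_CM = 76.8

# Published (basicranial length cm, total body length cm) estimate pairs:
# Dakosaurus maximus SMNS 82043, Plesiosuchus manselii NHMUK PV OR40103 and
# NHMUK PV R1089. Collinear to <1 cm, which is what lets a straight line
# reconstruct the underlying published scaling equations.
BODY_LENGTH_ANCHORS: tuple[tuple[float, float], ...] = (
    (83.1, 449.0),
    (100.0, 542.0),
    (125.5, 683.0),
)

# Denticle dimension maxima (apicobasal length, height, transverse width, um)
# of Dakosaurus maximus NHMUK PV OR35766 — the macroziphodont exemplar.
DAKOSAURUS_DENTICLE_UM: tuple[float, float, float] = (425.0, 330.0, 675.0)

# Isolated crown MUJA-1004 (cf. Plesiosuchus manselii): basal crown widths
# and mid-carina denticle densities.
MUJA1004_CROWN_APICOBASAL_MM = 10.3
MUJA1004_MESIODISTAL_MM = 4.9
MUJA1004_LABIOLINGUAL_MM = 4.2
MUJA1004_DISTAL_DENSITY_PER_MM = 6.0
MUJA1004_MESIAL_DENSITY_RANGE_PER_MM = (8.0, 10.0)

# 1-based indices of the 40 multistate characters scored as ordered
# (transformational sequences) in the second analysis of the 73 x 240
# thalattosuchian matrix.
ORDERED_CHARACTER_INDICES: tuple[int, ...] = (
    1, 7, 8, 10, 13, 25, 38, 39, 42, 43, 47, 50, 56, 58, 69, 86, 87, 96,
    126, 132, 133, 151, 152, 154, 156, 166, 179, 181, 182, 183, 184, 198,
    202, 214, 218, 225, 228, 230, 231, 237,
)

OUTGROUP_TAXON = "Postosuchus kirkpatricki"

# Published ensemble-index triples (CI, RI) for the two analyses; RC follows
# from the identity RC = CI * RI and is recomputed, never stored.
ENSEMBLE_TRIPLES = {
    "unordered": {"length": 627, "ci": 0.506, "ri": 0.860},
    "ordered": {"length": 667, "ci": 0.481, "ri": 0.863},
}
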