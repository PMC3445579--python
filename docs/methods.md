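# Methods

This note documents the models and procedures implemented in
`metriomorph`, the assumptions behind them, the parameters that matter, and
the numerical choices made where the design was genuinely open.

## Optimum gape geometry

The optimum gape is defined constructively in the lateral plane: (1) a
straight line is fitted across the tips of the dentary teeth; (2) the
parallel line through the jaw joint (glenoid) is drawn; (3) the gape angle
is the angle subtended at the glenoid by the tip of the posterior-most
dentary tooth, θ = atan(h/d), with *h* the perpendicular distance between
the two parallel lines and *d* the along-line distance from the glenoid's
projection to the posterior-most tooth tip's projection. *h* is the
optimum prey depth: it is the only length the two-parallel-lines
construction defines, and it makes the comparative table internally
consistent (depth = fraction × mandible length).

Choices and their rationale:

* **Tooth-line fit.** Total least squares (first principal axis of the
  tooth-tip scatter) by default: it is symmetric in x/y and exactly
  rotation invariant, which an ordinary y-on-x regression is not. An
  endpoints-only chord is available (`tooth_line_fit = "chord"`), since
  "a line across the tips" does not prescribe a fit.
* **Mandible length.** A measured value always takes precedence over the
  landmark-derived chord (anterior dentary tip to posterior retroarticular
  tip), because published comparative tables use measured lengths.
* **Units and signs.** Lateral view, anterior +x, dorsal +y; the angle is
  reported as an unsigned magnitude, so results are invariant to
  reflection and rotation of the input coordinates (verified to 1e-9).
* **Degenerate inputs.** Coincident tooth tips, or a posterior tooth tip
  that is not anterior to the glenoid along the tooth line (d ≤ 0), raise
  geometry errors rather than returning meaningless angles.
* **Rounding.** Reports round half-up: angle to the nearest degree, depth
  fraction to 1%, lengths to 2 decimals — matching the precision of the
  published table. All internal arithmetic is full precision; Python's
  banker's rounding is deliberately not used (0.15 × 87.5 = 13.125 must
  report as 13.13).

Standardised prey depth is fraction × 60 cm by default
(`reference_mandible_length_cm`), the conventional reference for
cross-species comparison.

## Allometric body-size estimation

Two stages:

1. basicranial length = mandible length × (76.8 / 80.9), the
   basicranial:mandible ratio of the most completely preserved reference
   skull ("*Metriorhynchus*" *brachyrhynchus* NHMUK PV R3804). The method
   assumes the basicranium and mandible of the target species scale in the
   same proportions as the reference taxon. Reported to 1 decimal.
2. total body length from an ordinary-least-squares straight line through
   the three published (basicranial cm, total length cm) calibration
   anchors (83.1, 449), (100, 542), (125.5, 683). The underlying published
   scaling equations are not reprinted anywhere accessible to this
   package; the three anchors are collinear to < 1 cm, so a straight line
   reproduces every published estimate at printed precision, and
   leave-one-out residuals are ≤ 0.02 m. The linearity of the original
   equations over this range is therefore an explicit, logged assumption.
   `max_residual_cm` is reported with every fit, and predictions outside
   the anchor range are flagged as extrapolations.

Internal unit is cm; metres appear only at the reporting boundary (2
decimals). No confidence intervals are produced — the anchors carry no
variance information.

## Ziphodont dentition

Macroziphodont: all three denticle dimensions (apicobasal length, height,
transverse width) strictly exceed 300 µm. Microziphodont: none exceeds
300 µm — "do not exceed" is read inclusively, so a denticle measuring
exactly 300 µm on every axis is microziphodont. Mixed patterns return
`indeterminate` rather than a guess; no described specimen shows one.
Classification is monotone (enlarging a dimension never moves the result
from macro toward micro) and threshold-exact. Compression ratio
(mesiodistal/labiolingual basal widths) reports to 2 decimals and denticle
densities (count/span) to whole denticles per mm, the precision at which
such measurements are published.

## Maximum parsimony

**Scoring.** Unordered characters cost one step per change between
distinct states; ordered characters (transformational sequences) cost
|i − j| on the integer state scale; no step matrices. Missing entries
("?" and "-" alike) contribute the full state set and can never add
steps. Binary trees score unordered characters by bitmask Fitch counting;
multifurcating trees and ordered characters use Sankoff dynamic
programming (the linear-cost transition uses a two-sweep distance
transform, O(k) per node). Both costs are metrics, so scores are
independent of root placement; the Fitch and unit-cost-Sankoff paths are
verified equal on random topologies, and scores are cross-checked against
dendropy's independent Fitch implementation. Identical character columns
are pattern-compressed with weights before scoring.

**Farris components.** Per character, m = minimum steps on any tree
(#observed states − 1 unordered; observed range ordered) and g = steps on
a star tree (n − max state frequency unordered; minimised absolute
deviation from a median hub state ordered). CI = Σm/L,
RI = (Σg − L)/(Σg − Σm), RC = CI·RI, reported to 3 decimals. All
characters are included by default (`include_uninformative=False` drops
characters with g = m); RI is refused when Σg = Σm.

**Search.** Seeded random-addition + SPR with plateau swapping: each
replicate adds taxa in a random order, always at the cheapest edge, then
walks the SPR graph — jumping to any strictly shorter neighbour, and
otherwise spreading breadth-first across equally short topologies (swap on
all shortest trees in memory) until no tree on the plateau has a shorter
neighbour. Plateau exploration and the pooled most-parsimonious-tree set
are capped at `max_saved_trees` (default 1000), with truncation flagged.
Heavier metaheuristics (sectorial search, ratchet, drift, tree fusion) are
out of scope: at the scales this package targets, plateau-swapping SPR
reproduces exhaustive-enumeration lengths on every random instance tested
(hundreds of 5–6-taxon matrices with mixed ordered/unordered characters and
missing data), which single-path SPR hill-climbing did not. Published MPT
counts and bootstrap percentages from heavier engines are search-effort
dependent and are not reproduction targets.

**Consensus and support.** Bipartitions are canonicalised as the leaf set
on the side not containing a reference leaf (the outgroup when set, else
the lexicographically smallest label), making all comparisons unrooted.
Strict consensus keeps bipartitions present in every tree; majority rule
keeps those in strictly more than the threshold (default > 50%; exact ties
are excluded) annotated with their frequencies. The nonparametric
bootstrap resamples characters with replacement (same count, ordered flags
carried along), reruns a reduced search per replicate, takes its
majority-rule consensus, and reports each clade's recovery fraction.
Bootstrap replicate streams are spawned from an independent child of the
run seed, so primary search and bootstrap never share randomness.

**Determinism.** Every stochastic operation derives its streams from one
integer seed via `numpy.random.SeedSequence` spawning; identical seeds give
byte-identical outputs.

## Synthetic data generators

*Mandibles.* The glenoid sits at the origin; the tooth line runs at
perpendicular offset h = d·tan(θ) with the posterior-most tip at along-line
distance d = 0.45·L by default (the offset implied by published gape
angles and depth fractions); teeth are evenly spaced over 0.4·L. The
noiseless construction is exactly inverted by the gape estimator (identity
to 1e-9). Noise is isotropic Gaussian per landmark, parameterised as a
fraction of mandible length so tests are scale free. Under the recovery
conditions used in testing (angles 5–30°, noise 0.5% of L, 200 mandibles)
the mean absolute angle error measures ≈ 0.88° (seed-to-seed sd ≈ 0.06°),
dominated by the tooth-line slope uncertainty over the finite tooth span.

*Character matrices.* A random (or supplied) unrooted binary tree with
equal branch lengths; each character receives a Poisson number of
substitution events per branch. Unordered characters jump to a uniformly
random different state; ordered characters take ±1 steps clipped to
[0, k−1]. Missing cells are masked uniformly at random. Defaults (240
characters, 3 states, 1/6 ordered, 10% missing) mirror the structure of
the real 73 × 240 thalattosuchian matrix this toolkit is sized for. The
simulator gives matrices with a known generating tree and controllable
homoplasy; it does not attempt realistic character correlation or
structured missingness, so recovery results speak to method correctness,
not to the behaviour of real morphological data.

*Problem sizes in the standard experiments* (chosen to characterise the
methods at desk scale): search-vs-exhaustive agreement uses 200 random
matrices of 5–6 taxa and 6–10 characters with mixed ordered/unordered
characters and missing data; tree recovery uses 12 taxa × 300 four-state
characters at 0.06 events/branch (≈ 1.3 expected changes per character
tree-wide — low homoplasy). Binary characters at comparable rates leave a
few seeds per twenty with legitimately tied or convergence-misled
branches; the four-state condition recovers the generating topology in
every seed tested while remaining well inside the low-homoplasy regime.

## Known limitations

* The gape construction is strictly 2-D; projecting a 3-D mandible into
  lateral view is the caller's responsibility.
* The body-length model is a two-parameter line through three printed
  anchors; outside 83–126 cm basicranial length it extrapolates and is
  flagged as such.
* The parsimony engine targets matrices up to desk scale (tens of taxa);
  it is exact-tested, not speed-tested, at 73 × 240.
* Polymorphic character codings are parsed but treated as missing, with a
  warning; inapplicable ("-") is not distinguished from unknown ("?").
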