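# Methods

## Fold morphometry model

A hemisphere in a coronal section is represented by its pial contour, an
ordered closed polyline in µm, normalised counter-clockwise.  The *outer
contour* is the morphological closing of the enclosed region by a disc
(default radius 1 mm, configurable; `inf` selects the convex hull).  Closing
reproduces a taut, hand-drawn envelope: it bridges every indentation
narrower than the disc and leaves convex stretches untouched, so the
envelope always encloses the section.  The closing is computed with
polygon buffering (dilate then erode, 32 segments per quarter circle),
which approximates circular arcs by chords to within ≈1.2 µm at the
default radius; enclosure tests therefore use a 2 µm tolerance.

*Local GN* counts the maximal contiguous arcs of the contour whose
distance to the envelope boundary exceeds a detachment threshold
(`gap_threshold`, default 50 µm).  No published numeric criterion exists
for "detached"; the threshold is explicit in the configuration and
recorded in every report.  Landmarks are derived from the same gap
profile: *gyrus tops* are midpoints of contact runs (gap below
`max(vertex spacing, 5 µm)`), *sulcus bottoms* are the gap maxima of
detached runs deeper than `min_depth` (default 50 µm), which also
suppresses noise bumps.

*Local SD* is the perpendicular distance from a sulcus bottom (by default
the deepest, standing in for the named reference sulcus that is identified
by eye in practice) to the line joining the two flanking gyrus tops.  When
the perpendicular foot falls outside the top-to-top segment the distance
to the infinite line is used, matching a ruler measurement along an
extended line rather than clamping to an endpoint.

*Local GS* is the area bounded by the pial arc between two sulcus bottoms
(by default the two deepest; ties resolve in contour order, which makes
them adjacent on generated sections) and the chord joining them.  Of the
two candidate arcs the one containing a gyrus top is taken, preferring the
shorter — for adjacent sulci that is the arc over the intervening gyrus.
Areas are unsigned (shoelace via polygon area).

All three metrics are divided EP/nonEP per section.  Per-animal values
average six sections for the GN ratio and three for the SD and GS ratios,
following the serial-section sampling scheme of the experimental design.

Known behaviour: the envelope dips into wide sulci by the disc (or hull)
sagitta, so the measured depth of a sulcus of width *w* on a hemisphere of
radius *R* underestimates the configured depth by ≈ R·(1−cos(w/2R)) with a
hull envelope (≈20 µm for w = 800 µm, R = 4 mm) and more for small closing
radii.  Depth recovery within 2 % therefore holds for narrow, clean sulci
with the hull envelope; the randomized acceptance run reports the realised
maximal relative error (typically 5–8 % across widths up to 900 µm).

## Progenitor classification and counting

Classification is total and mutually exclusive: Tbr2⁺ cells are IP cells
unconditionally (Tbr2 takes precedence because the IP definition is
marker-positive regardless of Pax6/HOPX co-expression, which is rare);
otherwise Pax6⁺ cells are HOPX⁺ or HOPX⁻ oRG by HOPX protein status, and
Pax6⁻/Tbr2⁻ cells fall to "other" and are excluded from the progenitor
denominator ("all progenitors" = Pax6⁺ and/or Tbr2⁺).  Cells with absent
Pax6 information also fall to "other" and are logged.

Intensity inputs are converted to calls by a strictly-greater threshold
("stronger than the threshold"); an intensity exactly at the threshold is
negative.  When no fixed threshold is supplied, Otsu's method on the
channel's intensity distribution is the default — original acquisition
thresholds are generally not recoverable from published material.  At a
4 σ separation between negative and positive component means, the best
achievable agreement with generating labels is 1−Φ(−2) ≈ 97.7 %; tests
assert agreement at the analytic Gaussian-overlap expectation rather than
a higher, unattainable figure.

Counting columns are rectangles 100–600 µm wide (300 µm for area
quantification) oriented perpendicular to the ventricular surface.  Column
edges are half-open (low edge in, high edge out), so adjacent columns tile
a region without double-counting — a convention the package fixes because
manual counting has none.  Derived statistics are plain quotients:
EP/nonEP cell-number ratio, gyral/sulcal region ratio, subtype proportions
(normalised over the three progenitor classes; they sum to 1 exactly) and
co-labelling fractions with single-marker or conjunctive predicates.
Cleaved caspase-3 and HOPX-mRNA analyses reuse the same two operations on
their channels.

## Laminar thickness

Thickness = band area / tangential length, with the tangential length
measured along the band's mid-arc (the average of the two long
boundaries; the published choice of curve is unstated, so the choice is
recorded in output metadata).  For a parallel-sided band this equals the
true width exactly, and for an annular sector the radial extent.  On
strongly folded bands the mid-arc lengthens along oblique fold walls and
the quotient reads a few percent below the radial band width; EP/nonEP
ratios of congruent geometry are unaffected.  Layer boundaries are inputs
(delineated from layer-marker stains upstream); no automatic segmentation
is attempted.

## Signal quantification

Positive area is the fraction of ROI pixels strictly above threshold
(pixel membership by centre-in-polygon), reported as proportion and as
areas; it is monotone non-increasing in the threshold.  Densitometry
relative expression is `(ctx signal/ctx loading)/(cb signal/cb loading)`,
invariant to rescaling both loading controls by a common factor and to
global exposure changes; setting the reference pair to (1, 1) reduces it
to the loading-corrected ratio used for immunoblots.  Per-cell in situ
intensities are divided by a reference-region intensity from the same
section before per-animal averaging.  No background subtraction is applied
by default (densitometry settings of published blots are unstated); a
rolling-minimum option exists in configuration.

## Statistics

The default test is the two-tailed pooled-variance Student's t from group
summaries, with SEM inputs converted to SD via SD = SEM·√n (the round trip
is exact).  This variant reproduces, at printed precision, 24 of the 57
published between-group comparisons shipped as reference data; the
remainder — largely within-animal contrasts — are not reproducible from
the printed summaries by any standard unpaired one- or two-tailed,
pooled or Welch variant (the published tests were presumably paired on
per-animal values that were not released, and printed rounding of means
and dispersions moves borderline p-values across their last printed
digit).  These are flagged in the reference table and reported at their
computed values rather than guessed at.  Welch and one-tailed variants are
available but non-default.  No multiple-testing correction is applied, as
none is described for the experimental design.  Degenerate inputs:
identical means with zero pooled variance give t = 0, p = 1; unequal means
with zero variance raise an error.

## Synthetic generator

The generator emulates the study conditions, not arbitrary data.  A
hemisphere outline is a radial curve r(θ) = R + noise(θ) − Σ bumps with
R = 4 mm; each sulcus is a cosine bump of configurable depth (600 µm
default) and width (800 µm default), clustered dorsally with 1.6
bump-widths spacing; smooth low-order Fourier noise models biological
irregularity.  The radial parameterisation gives closed-form landmark
truth (bottoms at r = R−depth on the bump axes, crests midway between
bumps) that detection must match within one vertex spacing.  Generation
rejects geometry whose physical fold walls would self-intersect: depth
≥ 80 % of the base radius, depth > 2× width, or overlapping bumps.

Laminar zones (CP 800, IZ 500, OSVZ 400, ISVZ 150, VZ 100 µm) and layers
(L2/3 300, L4 150, L5 200, L6 150 µm) are inward radial offsets of the
outline, so they follow folds.  Cells are homogeneous Poisson point
patterns per zone and class.  The default OSVZ baseline composition is the
prospective-sulcus composition of the system being modelled (6.1 % HOPX⁺
oRG, 49.4 % HOPX⁻ oRG, 44.4 % IP) at 2000 progenitors/mm² — the absolute
density is not published anywhere, and 2000/mm² is a realistic perinatal
germinal-zone figure chosen once.  Inside prospective-gyral angular
sectors the HOPX⁺ oRG intensity is multiplied by the gyral enrichment
factor (default 9.8, the published gyral/sulcal count ratio), implemented
by exact Poisson thinning so realised counts stay Poisson.  Co-labelling
markers are independent Bernoulli draws per cell with the published
fractions as default probabilities (Ki-67 ≈ 0.30–0.36 per class; EdU
0.222/0.124/0.327 for HOPX⁺ oRG / HOPX⁻ oRG / IP; HOPX mRNA in HOPX⁻ oRG
0.009); joint fractions are therefore products of marginals.  An intensity
mode replaces boolean calls with two-component Gaussian mixtures
(separation in σ units, default 4) and keeps the generating labels in
`*_true` columns for threshold validation.

What the generator does *not* emulate: realistic histology textures,
spatially correlated marker noise, 3-D structure, lineage dynamics over
developmental time, or segmentation error.  Passing tests therefore show
that the measurement pipeline is correct on data with the assumed
statistical structure — not that upstream image processing on real
micrographs would be error-free.  One small interaction is known: a
fixed-radial-window counting column at a gyral crest clips a few percent
of the fold-following OSVZ band near the bump shoulders, biasing the
recovered enrichment slightly low (≈9.4 for a configured 9.8); the pooled
recovery stays within 3 Poisson SE.

## Numerical conventions

Coordinates in µm, areas in µm², densities in cells/mm²; one global
convention.  Contours are normalised counter-clockwise on load; areas are
unsigned.  Ratios with zero denominators raise errors naming the offending
section or region rather than returning infinities.  Randomness flows
exclusively from the configuration seed through named, CRC-separated
generator streams, so every output is a pure function of the
configuration; reports embed a hash of the analysis parameters and contain
no timestamps, making re-runs byte-identical.  CSV is comma-separated,
'.'-decimal, UTF-8 with mandatory headers; floats are written shortest
round-trip and read with round-trip parsing.

## Problem sizes

Synthetic sections use 1440 contour vertices (≈17 µm spacing at R = 4 mm).
Validation runs use 20 randomized fold configurations for morphometry,
10 seeds with ≥2000 cells per class per seed for parameter recovery
(pooled estimates compared at 3 SE), and 512²-pixel fields for area
fractions — sizes at which binomial/Poisson uncertainty, not compute,
limits the checks.
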