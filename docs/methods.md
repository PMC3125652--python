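# Methods

`basalmorph` quantifies basal-layer keratinocytes in stratified squamous
epithelium from labelled microscopy rasters and compares three diagnostic
groups — normal buccal mucosa, oral leukoplakia and well-differentiated
squamous cell carcinoma (SCC) — with the classical morphometric toolkit.
This note records the models, conventions and numerical choices, and what
the synthetic validation does and does not establish.

## Measurement model

A case is represented by four per-case means in physical units: cell area
CA (µm²), cell perimeter CP (µm), nuclear area NA (µm²) and nuclear
perimeter NP (µm).  From these, three dimensionless descriptors are
derived:

* **form perimeter (form PE)** = 4·c·A/P², with circle constant c = π by
  default (a 22/7 variant is provided for compatibility with legacy image
  analyzers).  1 for a circle, lower for indented outlines.
* **contour index (CI)** = P/√A; 2√π ≈ 3.5449 for a circle, higher with
  indentations.  CI²·form PE = 4c identically, so the two descriptors carry
  the same information on different scales; every rank statistic is
  therefore identical between them, and every ANOVA/t statistic is
  invariant under the choice of c (a global positive rescaling).
* **N:C ratio** = NA/(CA − NA), the nucleus relative to the cytoplasmic
  remainder.

Measured data may violate the isoperimetric bound (form PE > 1): area and
perimeter are estimated by different discrete procedures, and the reference
cohort itself contains such rows.  Values above 1 are passed through with a
warning and never clipped.  Records with NA ≥ CA, by contrast, are
rejected at load with a per-row report: no plausible tracing produces them.

## Image measurement

Input is a pair of co-registered integer label rasters (cell mask, nucleus
mask; label k in the nucleus mask belongs to cell k) plus an isotropic
µm-per-pixel calibration.  Pixel centres sit at integer row/column
coordinates, origin top-left.

Each object's outer boundary is traced by marching squares at the 0.5
iso-level and smoothed with a short cyclic Gaussian (σ = 1.5 contour
samples).  The smoothing is load-bearing: the raw marching-squares ring is
a staircase whose length overestimates a circle's circumference by ~6%
regardless of resolution, which would destroy the circle anchors of the
shape descriptors.  With smoothing, rasterized disks of radius ≥ 20 px
measure within 0.5% (area, shoelace on the smoothed ring) and 0.3%
(perimeter, summed segment lengths).  The cost is rounded corners on
right-angled objects (~1 px of length per corner) and a few-percent
under-measurement of boundary length for deeply indented outlines whose
wiggles approach the pixel scale; areas remain within ~2% in all tested
regimes.  The raw pixel count is retained as an independent cross-check
estimator in the tests, never as the production path.

Cells touching the raster border are excluded (a partially visible outline
cannot be traced), as are cells without a nucleus label and labels that
are disconnected or contain holes (each with a logged reason).  Within each
field the ≤ 7 largest surviving cells by area are kept, mirroring the
acquisition protocol of selecting the 5–7 largest cells with clear
outlines per field; kept objects are averaged over all of a case's fields
into one record.  How per-case values summarise their 5–10 fields is not
dictated by the protocol; the arithmetic mean is assumed, with a median
option exposed.  No section-thickness (Holmes-effect) correction is
applied; measurements represent the sectioned profile as imaged.

## Synthetic histology

The generator exists so that every downstream stage is testable without
any external data.  It emulates the statistical structure the analysis
assumes, not histology's appearance: no staining, texture or 3-D
sectioning model.

Geometry is a star-convex radial perturbation: boundary radius
R·(1 + a·Σₖ wₖ cos(kθ + φₖ)) over harmonics k = 2…6 with weights ∝ 1/k
normalised to unit RMS, so the knob `a` (*irregularity*) is the RMS
relative radius deviation.  Amplitudes are fixed given the knob and only
the phases are random, so the resulting form PE is essentially a
deterministic, monotone, invertible function of the knob (computed by
quadrature, inverted by Brent's method).  Radial excursions are clipped to
[0.35, 1.9]·R so indentations stay wider than a raster pixel; without the
clip, extreme profiles pinch off into disconnected fragments at
rasterization.  The nucleus is a second star-convex polygon about the same
centre, rescaled toward `nucleus_fraction` × cell area under a pointwise
radial cap of 0.9 × the cell radius, which guarantees strict containment;
for large fractions the cap can bind and the realised nuclear area falls
slightly below target.  Cell polygons are rescaled analytically to their
target area (exact); cells are placed by rejection sampling with a
3-pixel clearance, never touching the field border.

The default parameter set is fitted to the packaged reference cohort:
10/30/30 cases, per-case CA and NA normal within group (truncated to
positivity and NA < CA, with the rejected-draw fraction tracked and < 1%
under defaults), nucleus fraction per case, and per-group irregularity
knobs obtained by inverting each group's mean form PE.  Group mean form PE
above 1 (the normal group's cellular value) is geometrically unreachable
and maps to a circle — a known, accepted mismatch between measured
convention and generative geometry.  Defaults elsewhere: 5–10 fields per
case and 5–7 cells per field (the emulated acquisition protocol),
512 × 512 rasters at 0.25 µm/px (the scale at which a ~150 µm² cell spans
~55 px, comfortably inside the estimator's convergence regime), 10%
within-case CV of per-cell area and 5% case-to-case CV of form PE.  The
protocol gives no within-field dispersion, so these two CVs are free
parameters of the emulation, fixed once at values typical for interactive
karyometry.  All randomness flows through one explicit seeded generator;
identical seeds give byte-identical ground-truth tables.

What passing the synthetic pipeline shows: the measurement path is
unbiased to well under a SEM at study sizes, the aggregation rules
preserve group structure, and the statistics detect the fitted effect
sizes with power ≈ 1.  What it does not show: robustness to segmentation
error, stain variation, overlapping or sectioned cells, or non-normal
per-case distributions — the masks are clean by construction.

## Statistics

Computed on per-case records only (the n = 70 design: df 2/67 for three
groups, 38 and 58 for the pairwise contrasts), never on per-cell
measurements.

* One-way fixed-effects ANOVA with the full SS decomposition; p from the
  upper F tail.
* Pooled-variance two-sample Student t (the published dfs force the pooled
  rather than Welch form), reported as a magnitude with two-sided p.
* Mann–Whitney U under the normal approximation, tie-corrected variance,
  no continuity correction by default (the convention that reproduces the
  reference Z values; the corrected variant sits behind a flag).
* Kruskal–Wallis H with tie correction; p from χ²(k − 1).

p-values are reported at full precision in JSON and rendered as `<0.0001`
below 10⁻⁴ in CSV tables.  No multiple-testing adjustment is applied,
matching the analysis being reproduced.  An "N:C cytoplasm" caveat worth
stating prominently: the reference report's pairwise "Cytoplasm" t rows
are reproducible from whole-cell area, not CA − NA (recomputation gives
17.01/18.54/11.71 vs the published 17.015/18.367/11.869 on CA, but
5.6/7.1/6.2 on CA − NA), so this package computes its cell-side area
comparisons on CA.

## Reconciliation with the published tables

The packaged cohort is the published per-case table transcribed verbatim,
so every statistic is recomputable.  Most entries agree to printed
precision (nuclear-area ANOVA F 193.505 vs 193.509; nuclear t tests
13.509/20.875/8.402; Mann–Whitney |Z| 4.467/4.560 vs 4.46/4.56).  Several
published cell-side entries are not reproducible from the published
per-case data by any route tried: cell-area between-SS 46,560.968
(recomputed 45,194.798; F 240.80 vs 240.09), cellular-CI F 18.122
(recomputed 18.841), N:C F 21.862 (recomputed 22.588), and a form-PE
Kruskal–Wallis χ² of 29.934 for both compartments (recomputed 24.875 and
24.424 — note the published report prints one identical value for two
different variables, and rank invariance explains the identical pairwise Z
values across form PE and CI but not an identical χ² across compartments).
The acceptance tests assert the reproducible entries tightly and the
inconsistent ones at tolerances matching the observed discrepancy,
documenting rather than forcing agreement.  The leukoplakia-vs-SCC
form-PE |Z| recomputes to 1.331 vs a published 1.36 with "P > 0.174"
(treated as P = 0.174 for display; recomputed 0.183).  An unattributed
N:C summary of 0.941 ± 0.182 in the source's discussion matches the
leukoplakia group's recomputed summary exactly; the per-group summaries
expose this rather than hard-coding it.

## Numerical conventions and degenerate inputs

Sample SD uses the n − 1 denominator; SEM = SD/√n; 95% CIs use the
Student-t quantile with n − 1 df.  Zero within-group variance, zero pooled
variance, or fully tied rank data raise explicit degenerate-data errors
rather than returning NaN.  Ties in rank tests are handled by midranks
with the standard Σ(τ³ − τ) corrections.  Polygon area is the absolute
shoelace value (orientation-free); degenerate polygons (< 3 distinct
vertices) are domain errors.  Aggregation ties in the "largest 7" rule are
broken by sort stability (first-encountered label wins); with ≤ 7 cells
per field, the rule is inactive on synthetic data.

## Problem sizes used in validation

The packaged-cohort analyses are instantaneous (n = 70).  The synthetic
end-to-end validation renders the full default design (70 cases, ~500
fields, ~3000 cells; about 1.5 minutes single-threaded), chosen to match
the emulated study's size exactly.  Law-of-large-numbers checks on the
tabular generator use 10⁴ cases per group; null-calibration of the tests
uses 2000 simulated datasets; Mann–Whitney enumeration oracles cover all
designs up to total n = 12.
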