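# Methods

This note documents the models, conventions, parameters and numerical choices
behind `grassaudit`, and what the synthetic-data tests do and do not show
about real data.

## Reference classification and harmonization

The reference vocabulary has 16 cover classes — six typed grassland forms
(open grassland, wooded grassland/savanna with ≤ 75% woody cover,
shrub-dominated grassland, tundra, planted pasture, sparse/barren grassland
with ≥ 5% grass cover), the special code `7` ("known grassland, type
unsure"), and nine non-grassland classes — plus `U` for unfilled cells.
Semantics follow the codes' stated meanings:

* `U` is excluded from every denominator: it is an absence of classification,
  not a classification.
* `7` counts as grassland in binary statistics (its grassland status is
  known) and is excluded at the simplified and full levels (its type is not).

Each product legend carries a total harmonization map into one shared
simplified scheme and a set of tokens counted as grassland.  Two default
mappings are judgement calls and are flagged `ambiguous` in the shipped
configuration: ESRI's merged `rangeland` class maps to grassland (it is the
only grassland-bearing class that product still has), and WorldCover's
`moss/lichen` maps to grassland (it is where tundra vegetation lands).  The
shipped class labels and harmonization tables are documented defaults, fully
overridable through the JSON scheme configuration; analyses that disagree
with either call can re-run with a different legend file.

Annotation cleaning normalizes whitespace and case, maps blank cells to `U`,
resolves the short entry codes (`1`–`7` and single letters) to canonical
codes silently, and corrects unrecognized tokens toward a supplied context
code (by default the sheet's majority entry) only when the token plausibly
extends it — e.g. `12` in a sheet of `1`s.  Every correction is logged with
provenance; unresolvable tokens are kept as `U` and flagged.

## Sampling frame

PSU grids are 10 × 10 blocks of a fixed global covering grid of pixels
10 m of arc tall (cell size 10/111,195 degree).  Cells are half-open
`[west, east) × [south, north)` so the tiling is exact; east–west cell width
is 10·cos(latitude) m, as with any fixed-degree high-resolution product.
A PSU snaps to the covering grid by centering on the pixel containing its
centroid, so any two centroids inside one pixel give the identical grid, and
overlap testing reduces to integer index-range intersection (exact and fast).

Additional PSUs are drawn areally uniformly over the site disc (r = R√u,
θ = 2πu on the local tangent plane, inverse-projected), then snapped.  A
draw is rejected and redrawn if the snapped grid falls outside the radius,
contains fewer than `min_grassland_pixels` (default 1 of 100) map-grassland
pixels, or overlaps any previously accepted grid — re-randomizing the most
recently placed grid, with a default cap of 1,000 attempts per PSU and an
error that names the dominant failed constraint.

Distances default to the haversine formula on a sphere of radius
6,371.0088 km; a WGS84 Vincenty geodesic is selectable (`model="wgs84"`).
The two differ by well under 0.6% — far below the precision of any statistic
here — and the implementation is cross-checked against an independent
geodesic library in the test suite.

## Dispersion statistic

The observed statistic is the mean over sites of the great-circle distance to
the nearest other site.  Because the appropriate null region for a global,
biome-constrained network is a modelling choice, the expectation is supplied
one of three ways: directly (auditing published summaries), by Monte-Carlo
complete spatial randomness over a bounding box (default; points uniform by
area on the sphere patch, expectation and s.e. from the replicate means), or
by the planar Clark–Evans closed form E[d] = 0.5/√(n/A) with
s.e. = 0.26136/√(n²/A).  The ratio observed/expected exceeds 1 for dispersed
networks; Z = (observed − expected)/s.e.

## Agreement statistics

Confusion matrices are oriented rows = map (predicted), columns = reference,
making user's accuracy a row quantity; the orientation is stated on the type
because the convention is frequently left implicit.  Undefined ratios (empty
row or column) return NaN, never 0, so "no pixels" is distinguishable from
"all wrong".  At the full reference level the matrix is rectangular — map
products cannot resolve grassland subtypes — so trace statistics (OA, κ) are
defined only at the binary and simplified levels, while the full level serves
per-class correct/incorrect counts.  Scale reports (PSU, location, overall)
are built from one shared label projection and grouped tallies, which makes
elementwise count conservation across scales structural rather than
incidental.

## Ratio correction and carbon

The corrected area multiplies a product's mapped global area by
p_ref / p_map.  Both proportions are computed over the same annotated sample
with the full record count as denominator, so the ratio reduces to
(reference-grassland count)/(map-grassland count); this sample-paired reading
keeps numerator and denominator on identical footing and is the default,
with the proportions also acceptable as externally supplied numbers.  The
estimator is consistent under representative sampling; under the
grassland-targeted design (core PSUs at grassland, 1/100 rule) it inherits a
small design bias that the method does not attempt to correct — the audit
reports the estimator as defined.

Coverage percentages use a configurable ice-free land surface of
131,319,290 km².  Carbon stocks are area × 100 ha km⁻² × density / 10⁹ in
Pg C, with the default density 51.5 t C ha⁻¹ (soil organic carbon, 0–30 cm).
Printed-value comparisons round half-away-from-zero on the shortest decimal
representation (`round_half_up`), matching how published tables are rounded.

## Synthetic studies

The generator emulates label-level processes only — no spectra, phenology or
imagery:

* **Landscapes**: categorical rasters from thresholding a Gaussian-smoothed
  noise field.  The field is smoothed with periodic boundary conditions
  (reflective padding would deflate edge variance and make class shares
  spatially non-stationary), standardized, mapped through the normal CDF to
  an approximately uniform surface, and cut at the cumulative class
  proportions.  `patchiness_cells` (default 40 cells = 400 m) sets the
  correlation length; `block_cells` (default 5) coarsens the noise field so
  paper-scale landscapes stay cheap; `patchiness = 0` gives i.i.d. cells.
  The default class mix carries 27% non-grassland, a planted-pasture share of
  grassland near 9% and wooded grassland near 11%.  Because the design
  targets grassland, annotated records run ~1–2 points below the landscape's
  non-grassland share.
* **Products**: per-true-class row-stochastic distributions over native
  product tokens.  Only a few rates are anchored to published per-class
  behaviour (wooded grassland found 65% of the time by the best product;
  lawns mislabelled grassland 59% of the time); the remaining rates are
  plausible stand-ins chosen so the aggregate binary accuracies under the
  default mix sit near the products' published levels (grassland producer's
  accuracy ≈ 0.86 / 0.22 / 0.26 for the WC-/LC-/DW-like models).
* **Annotations**: grassland cells flip to `7` at `unsure_rate` (default
  0.04); any cell becomes `U` at `unfilled_rate` (default 0.0005 — unfilled
  cells were vanishingly rare in practice, confined to two wholly unfilled
  grids).
* **Studies**: default 504 sites; `paper_psu_layout()` gives 340 sites with
  the full 11-grid design plus 164 single-grid sites (the documented regional
  clusterings), i.e. 3,904 grids / 390,400 pixels, within 1% of the published
  387,600 (the exact decomposition of that total is not recoverable from the
  main text).  All generators are pure functions of (spec, seed).

What passing tests show: the agreement engine tallies exactly (verified
against brute-force oracles), injected confusion rates are recovered within
binomial error, and the ratio estimator recovers true grassland area without
bias when sampling is representative while the raw mapped area is
significantly biased.  What they do not show: anything about spectral
confusion structure, geolocation error, or annotator disagreement in real
imagery — the generator produces label noise with known structure, nothing
more.

## Problem sizes and numerical choices

Test and acceptance runs use scaled study sizes chosen as the package's own
defaults for desk-scale verification: the estimator-recovery check runs 200
replicate studies of 6 sites × 6 PSUs at a 0.4-km radius with 3-cell
patchiness in the representative regime (uniform cores, no 1/100 rule, no
unfilled noise — isolating estimator consistency from the separate, tiny
unfilled-cell exclusion effect); sampler uniformity uses 10,000 seeded
placements with a Kolmogorov–Smirnov test of the uniform-disc radial law at
α = 0.01; the scale-conformance check simulates the full 504-site layout
once.  Landscape extents cover the site disc plus a 120-m margin.  Ratio
estimates are reported at full precision internally and rounded only for
display (areas to 0.1 million km², percentages to one decimal, stocks to two
decimals).

## Known limitations

* No variance estimators or confidence intervals for accuracies or corrected
  areas under the clustered two-stage design; point estimates only, as in the
  audit being reproduced.
* The published non-grassland accuracy figures are not internally consistent
  with the published counts under the definitional formulas (the counts imply
  more WC-grassland-labelled plus correctly-non-grassland pixels than exist);
  the package computes the definitional formulas and does not fit those
  figures.
* The full-level confusion matrix is rectangular by necessity; per-class
  κ-style statistics at that level are therefore out of scope.
* The ellipsoidal distance falls back to the spherical value for
  near-antipodal pairs where Vincenty's iteration does not converge.
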