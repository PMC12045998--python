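# Methods

This note documents the models, numerical choices and synthetic-data design
behind `aprmap`, and what the test suite does and does not establish.

## Grid and georeferencing

All products live on the European equal-area grid (EPSG:3035, ETRS89-LAEA on
GRS80, centre 52°N 10°E, false origin 4 321 000 / 3 210 000 m). Equal-area
matters: a 250 m cell is exactly 6.25 ha anywhere on the grid, so rates
[kg/ha] and zonal masses [kg] convert by a single constant and the
scenario-map construction conserves mass exactly. The projection
(forward and inverse, authalic-latitude formulation) is implemented in
`aprmap.geo` and validated against the published worked example of the
projection specification (50°N 5°E → E 3 962 799.45, N 2 999 718.85) and by
equal-area and round-trip property tests. Coarse rate grids may be supplied
in geographic coordinates (EPSG:4326); their cell centres are transformed
before the nearest-neighbour search. GeoTIFF I/O is implemented directly on
`tifffile` with the standard georeferencing tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory, GDAL_NODATA); only north-up axis-aligned
grids are supported.

## Crop-map fusion

Three pixel-wise corrections are applied to the fine crop raster against a
co-registered land-cover raster: land-cover rice wins over any crop label;
woodland/shrubland pixels identified as vineyards, fruit/berry plantations
or olive groves become orchards-and-grapes; grassland pixels identified as
pastures become pastures. The rules trigger on disjoint source codes, so a
single pass is order-independent (asserted by an idempotence test).
Upscaling assigns each 250 m pixel the modal code of its 25×25 block;
nodata pixels are excluded from the counts, an all-nodata block stays
nodata, and ties break to the smallest code (deterministic and
traversal-order independent; the choice is arbitrary but fixed). Partial
edge blocks are aggregated from the pixels available rather than dropped,
so no area is lost. Corrections run at fine resolution before upscaling.
Labels are then cross-walked to the eight mapped crop classes; Cotton and
Alfalfa cannot be separated from composite source labels and are excluded,
as are non-agricultural codes (mapped to nodata, with a logged warning for
codes absent from the crosswalk table).

## First-guess mass

Each ingredient's coarse rate grid is projected by nearest cell centre onto
the 250 m grid — for a regular lattice the nearest coarse centre is the
containing cell, so the lookup is a floor division after coordinate
transformation; target cells more than half a coarse cell outside the
coarse extent (configurable) are an error. Countries where an ingredient is
not authorized have its rate set to zero (not nodata: the mass sums stay
well-defined and dense); a missing (ingredient, country) authorization
record is an error rather than an implicit ban. The first-guess mass
m̃_mg(crop, country) accumulates rate × 6.25 ha over the pixels whose crop
class is in the ingredient's applicable set, pooling all non-Corn/Wheat
classes into AOC. Cell area is computed from the transform, not hard-coded.

## Reference-mass preparation

Usage records (country, crop label, chemical class, year, mass) pass four
ordered steps: (a) per-key mean over the 2015–2020 window (missing years
skipped, not zero-filled — the records are sparse in time and the window
centres the reference year); (b) restriction to chemical classes containing
at least one mapped ingredient; (c) crop-label pooling into Corn
(grain/green maize labels), Wheat (the four wheat-and-spelt labels) and AOC
(everything else, including soybeans and rice, whose separate areas are too
small to calibrate); (d) removal of masses strictly below 100 kg (the
boundary value is retained). Coverage fractions F* = selected/total per
(group, crop, country) quantify how representative the retained classes
are; ratios above one — an artefact of asynchronous reporting of groups and
classes — are discarded, and per-group aggregates F̄* are total-mass-weighted
means over the retained keys.

## Calibration

Per major group, the scaling model
m = k_C(crop) · k_L(region) · m̃^α is fitted by minimising the sum of
squared decadic-log residuals over the (crop, country) keys present in both
tables (keys in only one table are skipped and counted). Log residuals are
used because masses span many orders of magnitude. Minimisation is bounded
L-BFGS-B with the analytic gradient, from the all-ones start (so the first
guess is the starting model), bounds k ∈ [10⁻³, 10³], α ∈ [0.1, 2], and
tolerance 10⁻¹⁰ on J.

The model is gauge-degenerate: k_C → c·k_C, k_L → k_L/c leaves every
prediction unchanged, so only the nine products k_C·k_L and α are
identifiable. No constraint is added to break the gauge — the reported
seven-parameter vector is the optimizer's solution — and all recovery tests
compare products, never individual factors. The posterior covariance is the
Gauss–Newton approximation s²(GᵀG)⁺ with s² = J_min/(n − 7), where G is the
Jacobian of the log₁₀ predictions at the optimum; the pseudo-inverse
accommodates the exact rank deficiency introduced by the gauge (the normal
matrix is singular by construction, and a warning records this). The
negative log-likelihood is the Gaussian NLL at the ML variance
σ²_ML = J_min/n, i.e. NLL = (n/2)(ln 2πσ²_ML + 1); a perfect fit (J = 0)
is reported as −∞. Published parameter tables can be loaded as a
results-like object for uncertainty propagation without refitting
(`CalibrationResults.from_published`).

## Monte-Carlo scenarios

Parameters are sampled as independent normals centred on the estimates with
the posterior standard deviations as spread. Independence deliberately
ignores the (strong, gauge-induced) correlations: correlated sampling would
confine the draws to a lower-dimensional manifold, and the independent
choice is the cautionary one. Non-positive draws are rejected and re-drawn
(the model needs positive factors; rejection preserves unimodality better
than clamping, at the cost of a small upward bias when σ is comparable to
the mean). Each draw is propagated through the scaling model on every
first-guess key; the Low/Median/High scenario masses are the first
quartile, median and third quartile of the 10³-realization sample
(linear interpolation between order statistics — fixed so results are
reproducible). The convergence check recomputes the three statistics at
checkpoint sample sizes and reports their maximum relative change, per key
and for the aggregate (total-mass) sample; at the default 10³ realizations
the change between 500 and 1000 stays within a few percent.

## Scenario maps and quality index

Correction factors K = m_S/m̃ are resolved per (major group, calibration
crop, country, scenario) — the per-key resolution keeps the construction
mass-closed: summing APR_S × 6.25 ha over a (crop, country) zone and over
the group's ingredients returns m_S exactly (asserted to 10⁻⁶ relative).
Pixels of crop classes outside an ingredient's applicable set, and of
excluded classes, are nodata in its maps. A key without a factor (no
reference data survived preparation) falls back to the mean factor of the
same region, crop and scenario, with a logged warning.

QI = 1 − |m̂ − m*|/(m̂ + m*) uses the ML fitted mass m̂ (not the scenario
masses): it scores the calibration itself. It is symmetric, scale-invariant
and bounded in [0, 1]. Keys lacking reference data inherit the unweighted
mean QI of same-region same-crop donors, flagged `region_fallback`, and a
region without donors is an error. All ingredients of a major group share
the group's QI surface. Validation ratios R = m_S/m* use the scenario
masses and are ideally 1.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
the visual appearance of real landscapes:

* **Crop rasters** are field-structured: one class per 250 m block drawn
  from the class-frequency table (defaults echo the published surface-area
  shares, plus woodland and grassland pools that feed the fusion rules),
  with 10 % pixel speckle. The per-pixel marginal is exactly the class
  distribution, while block modes — what modal upscaling extracts — match
  the block draw. A purely iid pixel field would collapse under modal
  upscaling to the top one or two classes, which is neither realistic nor
  useful. The land-cover raster agrees with the crop raster except for
  planted disagreement patches that exercise each correction rule.
* **Countries** are contiguous column strips aligned with the upscaled
  grid (so the partition survives upscaling exactly), with widths on a
  geometric progression spanning roughly a decade: without a spread in
  country size the first-guess masses barely vary and the exponent α is
  poorly identified — mirroring the real spread of national cropland areas.
  A minimum width keeps the smallest country's masses above the 100 kg
  retention threshold at desk scale. Realistic country shapes are
  deliberately out of scope; the masks only need to induce a partition.
* **Coarse rate grids** are log-normal around a mean rate (default
  1.2 kg/ha full-scale, CV 0.4) on a coarse grid in geographic coordinates
  covering the fine extent, so the projection genuinely crosses a CRS
  boundary.
* **Usage records** are generated forward through the scaling model with
  known parameters per group, multiplicative noise 10^ε,
  ε ~ N(0, noise_sd_log10), and whole (group, crop, country) keys dropped
  at the sparsity rate. The target mass is disaggregated into equal shares
  over the group's chemical classes, split over two crop labels, and
  repeated for each year — so the preparation stage's averaging, selection
  and pooling logic is genuinely exercised — plus extra mass in an unmapped
  class (`<mg>88_88`, fraction 0.25) so coverage fractions fall below one.

Default full-scale conditions: 27 countries (the shipped region list;
the 28th member state is absent from the region definition and is accepted
only via an explicit override), 1875×2700 fine cells (10 m analog) upscaled
by 25, six ingredients spanning all three major groups and all calibration
crops, noise 0.3 decades (about a factor two), sparsity 0.15. The small
test fixture uses 4 countries, 150×150 cells at a 50 m analog (factor 5 to
the same 250 m), noise 0.2 and no sparsity — with only 12 reference keys
against 7 parameters it cannot afford dropped keys — and a higher mean rate
(2.5 kg/ha) so all masses clear the retention threshold. Everything is
deterministic from the scenario seed (per-ingredient streams are keyed by a
CRC of the ingredient name, not Python's randomized `hash`).

What passing tests show: the pipeline's algebra and bookkeeping are exact
(oracle equivalences, mass closure, parameter recovery to optimizer
tolerance at zero noise, honest posterior spread under noise). What they do
not show: robustness to satellite classification error structure, temporal
crop rotation, reporting biases in real usage statistics, or the realism of
any particular rate surface — none of which the generator emulates.

## Numerical and degenerate-input conventions

* Modal ties → smallest code; all-nodata blocks → nodata.
* Nearest-neighbour ties at cell boundaries resolve to the cell containing
  the point (floor convention); measure-zero for generic grids.
* Authorization: banned → rate 0; missing record → error.
* Reference filter boundary: mass = 100 kg is retained.
* J = 0 → NLL sentinel −∞; n ≤ 7 observations → posterior-σ error.
* Scenario quartile estimator: linear interpolation; n ≥ 4 required.
* Relative-convergence statistics are undefined (error) when a checkpoint
  statistic is zero.
* Output tables are sorted by (group, crop, country[, scenario]) and runs
  are reproducible from config + seed; the Monte-Carlo seed is recorded in
  the output metadata.

## Known limitations

* The taxonomy fixture enumerates 36 chemical classes (the printed table's
  rows); the accompanying text of the source data speaks of 37 — the
  discrepancy is preserved, not resolved.
* The seven-parameter calibration is reported in the optimizer's gauge;
  per-parameter standard deviations are meaningful only through the
  pseudo-inverse construction and should be read jointly with the gauge
  note in the summary.
* Scenario independence of parameter draws overstates spread along the
  gauge direction (a draw may move k_C up and k_L up simultaneously, which
  correlated sampling would suppress); this is the intended cautionary
  behaviour.
* The CLI's `make-maps` stage re-runs the pipeline from the configuration
  rather than resuming from intermediates; stage-level resumability is at
  the granularity of the written products.
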