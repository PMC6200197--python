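# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `microsdm`, stage by stage.

## Terrain analysis

**DEM gridding.** Scattered (x, y, z) survey points are triangulated
(Delaunay) and linearly interpolated at cell centres; cells outside the
convex hull are nodata. Linear barycentric interpolation reproduces any
affine surface exactly, which is the correctness anchor used in the
tests. Default cell size 0.1 m. The grid origin is the min-x/max-y corner
of the point cloud; row 0 is the northernmost row and cell values refer
to cell centres. Coordinates are a local planar system in metres — no
geodetic transforms, appropriate for extents of tens of metres.

**Slope and aspect.** Horn's 3×3 finite-difference stencil; slope in
degrees, aspect in degrees clockwise from north pointing downslope.
Border cells and cells adjacent to nodata are nodata. Zero-gradient cells
carry a flat flag (−1) and reclassify to insolation code 1 (shady): a
flat cell enjoys no aspect-driven insolation advantage, and the shady
class is the conservative assignment. The four aspect codes are
1 shady (0–45°, 315–360°), 2 half-shady (225–315°), 3 half-sunny
(45–135°), 4 sunny (135–225°); a boundary angle joins the
higher-numbered band.

**Topographic position index.** For each cell, raw TPI is the focal
elevation minus the mean elevation of valid cells whose centres lie
within the neighbourhood radius (default 1 m; focal cell excluded).
Standardised TPI divides by the SD of those neighbourhood elevations, so
the classification thresholds are in local-relief units; a global-SD
variant and a focal-inclusive variant are available behind flags, since
conventions differ between implementations. Neighbourhoods with zero SD
return a standardised TPI of 0 (a flat patch is at its neighbourhood
level by definition); cells with fewer than 3 valid neighbours are
nodata. Near the raster border the disc is truncated; on a trended
surface this biases TPI within one radius of the edge — an inherent
property of neighbourhood TPI, and the reason band-structure checks in
the tests ignore a 1 m margin.

**Landform classification.** Six classes from (standardised TPI, slope):
valley ≤ −0.3 < lower slope ≤ −0.05 < {flat, middle} ≤ 0.15 < upper
slope ≤ 0.4 < ridge, with flat vs middle split at slope 7° (flat ≤ 7°).
All upper bounds are inclusive. The middle-slope band is read as
−0.05 < TPI ≤ 0.15 with slope > 7°, the only reading under which the six
criteria partition the (TPI, slope) plane; a property test sweeps
threshold-straddling values to confirm totality and exclusivity.

**Rasterisation and areas.** Polygons rasterise by the centre-point rule
(cell = 1 iff its centre is inside), the natural inverse of converting a
raster to points. `patches_from_mask` inverts this exactly (unions of
cell squares), so patch polygons round-trip through rasterisation without
losing cells. Class areas are cell counts × cell area; percentages are of
the masked total and sum to 100 by construction.

## Geostatistics

Factors are interpolated by ordinary kriging. The empirical semivariogram
bins half squared differences of all point pairs into 12 lags up to half
the maximum pairwise distance; a spherical model (nugget, partial sill,
range) is fitted by least squares weighted by pair counts. Spherical is
the default family — the common default of GIS geostatistical tooling —
with exponential and Gaussian available; for the latter two the fitted
range is the practical range (95% of the sill). Parameters are bounded to
the data's scale (range ≤ 10× the maximum lag, sills ≤ 10× the maximum
semivariance): beyond those bounds the parameters are unidentifiable from
the data, and the bounds keep flat or noisy variograms from drifting.
Anisotropy is not modelled.

The kriging system (semivariance matrix plus Lagrange multiplier) is
solved densely for all target cells at once; weights sum to 1 per cell
(unbiasedness), and with a zero nugget the predictor interpolates the
samples exactly — both enforced in tests against an independently
assembled dense solve. Exactly duplicated sample locations are averaged
before solving; a numerically singular system receives a 1e-10 diagonal
ridge (logged) before failing hard. Cells receiving negative weights are
permitted and logged.

Validation is leave-one-out: mean prediction error (MPE, factor units,
ideally near 0) and RMS standardised prediction error (RMSSE, ideally
near 1). No numeric pass/fail gate is imposed on either — with 54
spatially clustered points the statistics are reported, not judged. A
constant ("degenerate") factor is interpolated as its constant with zero
variance and flagged.

## Presence–absence model

The reference SDM is a binomial GLM with logit link on z-scored factors,
fitted by IRLS (maximum likelihood); with ``l2 > 0`` a ridge-penalised
Newton solver is used instead (the penalty makes the Hessian positive
definite, so full Newton steps converge even on a perfectly collinear
design). Standardisation constants are
estimated from the training cells and stored with the model, so
prediction on new stacks uses the training scale; coefficients are
reported on both the z-score and raw scales. Constant-in-training
factors are dropped and named. Perfect separation raises a typed error
advising an L2 penalty; with `l2 > 0` the fit is ridge-penalised
(intercept unpenalised), trading unbiasedness for existence. Class
imbalance is left unweighted. The four-way ordinal aspect code enters as
a single numeric factor.

Skill is the training-data AUC (rank-sum formulation), banded
excellent/good/fair/poor/fail at 0.9/0.8/0.7/0.6 with boundaries joining
the higher band; model selection keeps the highest-AUC candidate above
the 0.9 gate and fails loudly, listing all AUCs, when none qualifies.
AUC is computed on the calibration data, as labelled in all reports — no
holdout is taken. Alternative model families (maximum entropy, neural
networks, SVMs) can be supplied through the same fit/predict contract
but are not implemented.

Factor importance is permutation AUC-drop: the mean loss of training AUC
over k seeded shuffles of one factor column (default k = 3 in the
pipeline). With 26 strongly inter-correlated factor fields, permutation
importance spreads credit across correlated factors; rankings should be
read by factor group rather than as sharp orderings.

## Restoration scenario

The scenario stack replaces the values of the replaced factors (default:
all soil and microclimate factors) inside trench footprints
(centre-point rule) with per-factor reference values; every other cell,
and the topographic layers everywhere, are bit-identical to the input.
In synthetic runs the reference values are the means of the kriged
factor layers over valley presence cells — the species' core habitat,
standing in for reference-stand measurements. Taking them from the
kriged layers rather than the true fields keeps the replacement vector
on the scale, and inside the data range, the model was calibrated on:
it is then a convex combination of training rows, so the in-trench
linear predictor equals the mean training predictor of core-habitat
cells and is stable even when collinearity makes individual
coefficients large and mutually cancelling. True-field means sit
beyond the kriged layers' range (interpolation shrinks extremes), where
those cancelling components dominate and the constant in-trench
prediction becomes arbitrary.

The scenario probability map is cut at t_low = 0.5 and t_high = 0.75
into unsuitable / sub-suitable / suitable. The thresholds are a design
choice (0.5 is the model's decision boundary; 0.75 marks the upper half
of the presence-favoured range) and are echoed in every output, since
reported areas are only interpretable alongside them. Area accounting is
conservative by construction (class areas sum to the valid total for any
thresholds), and a strata report cross-tabulates suitability against
{trench footprint, valley, other} both as shares of each class and
shares of each stratum.

## Field statistics

Normality uses the Lilliefors variant of the Kolmogorov–Smirnov test
(parameters estimated from the sample; p-values from the statsmodels
table), labelled as such because statistical packages differ silently on
this point. Homogeneity uses Levene's test on absolute deviations from
group means (mean-centred variant). The group comparison is one-way
ANOVA with unadjusted LSD pairwise t-tests on the pooled within-group
MSE — no further multiple-testing correction, matching standard
field-ecology reporting — with an optional natural-log transform that
requires strictly positive data. Letters come from the insert-and-absorb
compact letter display, processing groups in descending-mean order so
'a' marks the largest mean; the output satisfies, and a property test
enforces, the display invariant: two groups share a letter iff their LSD
p ≥ α.

## Synthetic study system

The generator emulates a degraded gullied hillslope of the kind the
pipeline targets; all generators are pure functions of (spec, seed).

**Terrain.** `z = base_slope·y + A·(y/Ly)·cos(2π·n_gullies·x/Lx) +
N(0, σ)` sampled at quasi-uniform points with a 0.05 m minimum-spacing
rejection rule (keeps the triangulation well-conditioned). The downslope
amplitude taper mimics erosion gullies deepening downslope and leaves a
planar crest zone — without it, low-TPI cells coincide with the cosine
inflection points where the cross-slope gradient peaks, and the
flat-slope class never occurs. Defaults: 24 m × 24 m (≈576 m², the scale
of the studied plot), 3 gully periods, amplitude 1.2 m, base slope 0.12
(≈6.8°, so the crest zone straddles the 7° flat/middle cut), survey
noise 0.02 m, 3,358 points.

**Factor fields.** Each of the 26 factors is affine in standardised TPI
— sign per its observed valley→ridge gradient (soils warmer/drier/
poorer/less acid ridge-ward in the growing season; winter moisture
reversed), mean and amplitude per realistic field values — plus a
spatially correlated Gaussian noise field (smoothed white noise, 4 m
correlation length, magnitude matching within-landform variability of
field data). The correlated noise matters twice over: white per-cell
noise at 0.01 m² resolution is physically implausible for soil and
microclimate, and it would make interpolation from 54 points
structurally uninformative — i.e. the pipeline's own method would be
inapplicable to its own test data.

**Presence.** Bernoulli draws from a logistic response on z-scored
factor layers. The bundled response puts weight −3 on growing-season
soil temperature, +3 on spring soil moisture and +2 on total nitrogen
with intercept −2 — the factor groups that dominate the species'
distribution in the field, strong enough that the calibrated model's
discrimination (AUC ≈ 0.90–0.92 across seeds) matches what is reported
for the real system, with roughly 1:2 presence:absence imbalance.

**Sampling design.** 9 cells per landform class (valley / slope / ridge,
slope pooling codes 2–5) per gully type, with gully types split as the
west and east halves of the extent — 54 points, mirroring a paired
gully survey.

**Trenches.** Non-overlapping 4.0 m × 0.5 m rectangles oriented along
local elevation contours (long axis perpendicular to the coarse DEM
gradient), placed by bounded rejection sampling at 600 per hectare. The
real trench layout of such plantations is not published; contour
alignment is the defining feature being emulated.

**What the synthetic system does not emulate.** Real hypsometry and
exact field values; measurement error in factor assays; temporal
dynamics (the 10-minute microclimate series is generated directly as
period summaries); spatial autocorrelation of presence beyond what the
smooth factor fields induce; observer effects in patch mapping. Passing
tests therefore demonstrate the pipeline's internal correctness and its
behaviour under topography-driven habitat structure, not field validity.

## Ground-truth recovery diagnostic

Synthetic pipeline runs refit the generating model — the response's own
factors, true fields — and compare coefficient signs against the known
response (the standard simulation-study recovery design). Refitting
against all 26 near-collinear layers instead would confound recovery
with collinearity-driven identification noise. The headline calibration
(on kriged layers plus topography) is reported separately and is the
model all predictions use.

## Problem sizes and numerics

The default study system is a 240 × 240 grid (57,600 cells) from 3,358
points; the test suite exercises a 120 × 120 fixture. The pipeline runs
in well under a minute on one core at full size. Kriging solves one
55 × 55 system per factor against all cells at once; TPI uses FFT-free
discrete correlation with a disc kernel. IRLS runs to a 1e-8 deviance
tolerance with a 100-iteration cap; fits report a converged flag, and
coefficient magnitudes above 1e4 on the z-score scale are treated as
quasi-separation. Determinism: identical config + seed reproduces
summaries bit-for-bit; every stochastic component draws from its own
seeded generator derived from the run seed.

## Known limitations

* Training-data AUC overstates transferable skill; no spatial
  cross-validation is performed (by design, matching the evaluation
  protocol being reproduced).
* Kriging from 54 clustered points cannot recover fine-scale factor
  variation; the RMSSE below 1 in synthetic runs reflects the smooth
  noise fields being easier to predict than the fitted variogram
  expects.
* TPI and slope are biased within one neighbourhood radius of the
  raster border.
* The suitability thresholds are conventions, not estimates; areas
  should be compared across scenarios at fixed thresholds, not read as
  absolute habitat amounts.
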