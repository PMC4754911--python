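# Methods

This note documents the models, estimators and numerical choices behind
`phenopipe`, and what the synthetic-data generator does and does not
emulate.

## Fluorescence: per-pixel photosystem II operating efficiency

Each acquisition yields three frame stacks per camera position: 24 frames
under steady actinic light (averaged → Fs), 6 frames during a saturating
pulse, and 24 frames with the measuring LEDs off (averaged → dark).  The
Fm′ image is the single saturating frame with the highest **total** signal
(ties → earliest frame).  Treating one whole frame as Fm′, rather than a
per-pixel maximum, avoids stitching an image out of frames taken at
different instants of the pulse; a per-pixel-max mode exists behind the
`per_pixel_max` flag for comparison.

A broadband fluorescent target imaged under both illumination regimes
gives the lamp-intensity correction `factor = mean(target@saturating) /
mean(target@actinic)`.  Only the ratio of the two measuring intensities is
identifiable, so which image the factor multiplies is a convention; here
it multiplies the dark-subtracted Fs:

    Fs_c  = (Fs − dark) × factor
    Fm′_c = Fm′ − dark
    Φ_PSII = (Fm′_c − Fs_c) / Fm′_c, clipped to [0, 1]

The dark image is subtracted from both signals (it estimates additive
background light).  Pixels with `Fm′_c ≤ noise_floor` (default 5 intensity
counts; configurable) are flagged invalid and carry NaN — background has
no fluorescence denominator worth dividing by.  Clipped pixels are
counted in `EfficiencyImage.n_clipped` rather than silently discarded.

Histogram bin edges are rounded to 12 decimals so that a value of exactly
0.7 falls in the [0.7, 0.8) bin despite binary floating point.

## Spectral indices and projected leaf area

The chlorophyll index is `(1/R700 − 1/R790) × R790`, algebraically
`R790/R700 − 1`.  Pixels with either band ≤ ε = 1e-4 reflectance are
invalid: the reciprocal of near-zero background reflectance is meaningless
and numerically explosive.  Counts-to-reflectance calibration is a single
linear gain per band against a white reference (`calibrate_band`); no
radiometric model beyond that is attempted.

RGB composites map 660/570/480 nm to R/G/B and scale all three channels by
one common factor, preserving hue (equal bands render grey).

Projected leaf area is `mask pixel count × pixel area`; it depends only on
the mask, so it is invariant to intensity rescaling of the NIR image.  The
default pixel area derives from the 60 mm plant pitch and the configured
box size in pixels.

## Segmentation

Grid reference lines (including the image edges) partition a tile image
into half-open boxes `[r0,r1) × [c0,c1)` — half-open so the 12 boxes tile
the image exactly once.  The plant mask inside a box is `pixel >
threshold`, with the threshold either user-set or Otsu's method computed
within the box (on a constant patch Otsu is undefined; the mask is then
empty).  Masks for efficiency summaries are taken from the fluorescence
signal itself (dark-subtracted Fm′), masks for area and chlorophyll from
the NIR image; both sources are interchangeable in the run configuration
because they agree to Jaccard ≥ 0.95 on well-exposed plants.  No
morphological cleaning runs by default; `min_object_px` optionally removes
specks.  Pixel outliers are not trimmed before averaging.

## Growth curves

Per-plant area series are fitted with P-splines: a cubic B-spline basis on
equally spaced knots (one segment per observed day, at least 10) with a
second-order difference penalty on the coefficients,

    min ‖y − Bθ‖² + λ‖D₂θ‖².

The second-order penalty leaves straight lines unpenalised, so a noiseless
linear series is interpolated at any λ and the λ→∞ limit is the ordinary
least-squares line — both are used as exact test oracles.  λ is chosen by
generalized cross-validation on a 61-point log grid 1e-4…1e8 unless fixed.
Knots come from `linspace` so the boundary knots equal the data endpoints
exactly (avoiding out-of-domain errors at the last observation).

Slopes are central finite differences of the fitted curve on a 2001-point
grid; the relative growth rate is slope/fitted and requires positive
fitted values.  The 3-hourly percentage change `100·(v_{i+1} − v_i)/v_i`
is deliberately computed on the **raw** series: it is the leaf-movement
statistic, and smoothing it away would defeat its purpose.  Zero
denominators yield NaN entries, flagged not raised.

## Variance components, BLUEs, heritability

The design model for one trait at one time point has a fixed intercept and
check-genotype factor, and independent random effects for genotype,
experiment, basin, platform row (x) and column (y), camera position
(tile), within-image row and column, plus the second- and third-order
interactions involving experiment.  For single-experiment tables all
experiment terms are dropped; single-level terms are dropped with a
warning.

REML estimation uses Fisher scoring on the variance scale with three
safeguards: an active set (components pinned at zero whose score points
outward are frozen for that iteration, preventing boundary thrashing),
step-halving line search (monotone ascent), and an EM fallback step when
the scoring proposal fails.  Convergence is a relative log-likelihood
change < 1e-8 within 500 iterations; standard errors come from the inverse
Fisher information.  Negative estimates are truncated at zero (reported as
exact 0).  The n×n covariance matrix is handled directly — platforms of
this size stay in the low thousands of plants per time point.  On balanced
one-way designs these REML estimates equal the closed-form ANOVA
estimators, which the tests exploit as an independent oracle.

BLUEs refit the model with genotype as a fixed cell-means factor and the
genotype-free design terms random, then solve generalized least squares
under the implied covariance.  Random interactions involving genotype are
omitted once genotype is fixed (a modelling choice: with genotype fixed,
its interactions are no longer exchangeable draws; their default variances
are zero anyway).  Check genotypes participate in every fit but are
excluded from genotype-level outputs.

Broad-sense (plot-level) heritability uses the classical ANOVA route: an
ordinary linear model with fixed effects for basin nested in experiment,
within-image row and column, and genotype entered **last** (sequential sum
of squares, so MS(G) is adjusted for the design factors), then

    σ̂²G = max(0, (MS(G) − MS(E))/r̄),  H² = σ̂²G/(σ̂²G + MS(E)),

with r̄ the harmonic mean of per-genotype replicate counts (the classical
effective replicate number for unbalanced data).  The 95 % interval
inverts the F pivot (a Knapp-type bound): under the balanced random-model,
`F/(1 + r̄σ²G/σ²E) ~ F(df_G, df_E)`; the two quantile inversions are mapped
through `H² = λ/(λ + r̄)`.  A bootstrap-over-replicates interval is
available via `ci_method="bootstrap"`.

**Known finite-sample bias.** H² is a truncated ratio of mean squares, so
its expectation is below the generating value: at 20 genotypes × 4
replicates with σ²G = σ²E the exact expectation (by integrating the
central-F sampling distribution) is ≈ 0.484 rather than 0.500.  The
acceptance checks compare Monte-Carlo means against this closed form.
Similarly, the ANOVA estimates the *realized* variance of the genotype
effects actually present in an experiment, which fluctuates around the
nominal σ²G by a χ²_{k−1}/(k−1) factor; recovery of a programmed H²(t)
time course is therefore assessed against the realized truth, which the
generator reports alongside the nominal one.

## The synthetic platform

The generator emulates: the 120-tile × 12-plant layout with two basins;
randomised genotype-to-position assignment per experiment; the daily
schedule (efficiency at 1, 4 and 7 h into a 10-h photoperiod, NIR every
3 h → 11 mask-bearing images per day); additive Gaussian design effects
with configurable variances per term; genotypic and residual efficiency
variance of the same order (defaults σ²G = σ²E = 6.25e-4, i.e. genotype
SD 0.025 around a mean of 0.67 at 200 µmol m⁻² s⁻¹ light or 0.585 at
550); a chlorophyll index that decreases at high light; logistic rosette
growth (5 mm² initial area, 0.008 h⁻¹ rate with 8 % genotypic CV, 2000 mm²
cap, measurements starting 14 days after sowing) modulated by a diel
leaf-movement sinusoid (5 % amplitude, halved in the day and halved again
at high light); optional "extreme" genotypes — one with mean efficiency
0.35, one with a linear within-photoperiod efficiency decline — and an
optional sinusoidal modulation of the genotype-effect scale that programs
a diel H²(t) oscillation.

Rendered images draw each plant as an 8-lobed rose curve of the correct
area (any controllable-area silhouette would do), with on-plant maximal
fluorescence of 400 counts, a dark offset of 10 counts, a configurable
actinic/saturating lamp ratio encoded in the target patch, reflectance
bands inverted from the chlorophyll index at fixed R790 = 0.5, and
optional Gaussian read noise.  In the noiseless case the image pipeline
recovers efficiency and chlorophyll to machine precision and area to
within rasterization error.

Not emulated: optical point-spread and defocus, specular highlights,
touching or overlapping rosettes, leaf-angle-dependent reflectance,
heteroscedastic or spatially correlated residuals, stress and disease.
Passing tests therefore demonstrate correctness of the computational
chain, not robustness to every optical artefact of real hardware.

## Problem sizes and runtime choices

Tests and the acceptance script use deliberately scaled designs: 20
genotypes × 4 replicates for Monte-Carlo recovery (200 seeds), 24
replicates for the H²(t) time course (the full platform supports 72), one
rendered tile rather than 120 for image round-trips, and 50 seeds for the
extreme-genotype sign test.  These sizes give Monte-Carlo errors an order
of magnitude below the assertion tolerances while keeping the whole suite
in well under a minute.  The `paperlike` fixture writes tables for the
full 1440-plant platform; image rendering for it is generated on demand
rather than persisted.

## Known limitations

- The REML implementation targets independence-structured random terms;
  spatially correlated (e.g. AR×AR) residuals are out of scope.
- Otsu thresholding assumes a bimodal intensity histogram inside each box;
  an empty position yields an empty mask, flagged downstream.
- The F-pivot confidence interval is exact only for balanced one-way
  designs; for unbalanced data it is the usual approximation.
- Growth fitting needs at least `degree + 2` observations per plant;
  shorter series are skipped with a warning rather than fitted badly.
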