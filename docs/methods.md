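# Methods

This note documents the models, estimators, numerical choices, and known
limitations of the package. Nothing here reports an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Conventions

Pixel coordinates are 0-based, row-major, origin at the top-left; polylines
are stored as (x, y) = (column, row). Fiber orientations are axial
(undirected), measured from the +x axis in degrees on [0°, 180°), with the
y axis pointing down the image rows. Time is months throughout; the
"5-year" horizon is 60 months. The default ROI geometry is a 150 µm field
of view; `read_shg_image` defaults to 150/512 ≈ 0.293 µm/px, and simulated
ROIs derive their pixel size from the requested grid so the field is always
150 µm.

## Image simulator

Fibers are circular arcs. A fiber is parameterized by arc length L, width
w (the FWHM of its Gaussian intensity profile), peak intensity, axial
orientation θ, and a total turning angle φ ("curvature"); φ = 0 gives a
straight segment. This parameterization makes ground-truth straightness a
closed form, chord/arc = sin(φ/2)/(φ/2), which the tests exploit.
Orientations are drawn from a von Mises distribution on the doubled angle
(concentration κ_θ; κ_θ = 0 is uniform), the correct null family for axial
data. Crosslinks are realized by branching a new polyline off a parent
fiber at a uniform arc position, matching the skeleton branch-point
definition used downstream. Rendering accumulates Gaussian-profile strokes
(σ = w/2.355 so the FWHM equals the nominal width); the ground-truth mask
marks pixels within w/2 of a centerline. Noise is optional Poisson shot
noise followed by additive Gaussian read noise, clipped to [0, 65535].
Fibers whose polyline leaves the field are clipped to their longest
in-bounds run, so ground-truth arc lengths of clipped fibers are shorter
than the drawn L; tests that rely on the closed-form straightness filter to
unclipped fibers.

Archetype presets (patterns 1–8) differ from a common base only in the
parameter that defines the pattern: high curvature (1), concentrated
orientation parallel (2) or perpendicular (3) to a declared boundary axis
at 0°, a high branch rate (4), high (5) versus zero (6) orientation
concentration, and high (7) versus low (8) fiber count. The presets were
chosen once so that ground-truth orderings (area 7 > 8, straightness 1 < 2,
concentration 5 > 6) hold by construction.

## Segmentation and network tracing

Segmentation is Gaussian smoothing (default 0.4 µm) followed by the global
threshold maximizing between-class variance (Otsu). An all-zero ROI yields
an empty mask; a constant positive ROI has no defined threshold and raises
a degenerate-input error.

Tracing skeletonizes the mask and builds an 8-connected pixel graph,
*omitting* diagonal edges that close a triangle with an orthogonal pair —
without this, every diagonal contact with a line manufactures a spurious
junction. Spurs shorter than 3 µm (default) ending at a junction are pruned
iteratively. Skeleton pixels of degree ≥ 3 are junction pixels; adjacent
junction pixels are merged into one crosslink at their centroid. Fibers are
maximal degree-2 chains between endpoints/junctions, and two chains meeting
at a crosslink are joined when their incoming tangents (estimated over the
5 nearest pixels) continue within 20° — greedy best-angle pairing, so a
plus-shaped crossing traces as two through-fibers with one crosslink.
Traced polylines are smoothed with a 5-point moving average (endpoints
pinned) to remove the staircase inflation of pixel-chain arc lengths
(up to ~8% for oblique fibers); fibers shorter than 5 µm are discarded.

Morphological features follow the definitions in the README. Two
bias-corrections matter: fiber width is 2 × the mean Euclidean distance
transform along the skeleton *minus one pixel*, correcting the half-pixel
overshoot at both mask boundaries; with it, single-fiber fixtures recover
the generating width and length within one pixel-equivalent. Empty networks
return all-zero sentinel features (not NaN) so Z-scoring never propagates
missing values; patients whose every ROI is too sparse to trace are
expected to be excluded upstream. Crosslink spacing snaps crosslinks to
fiber vertices within 2 px and averages consecutive arc-length gaps over
fibers carrying ≥ 2 crosslinks (0 if none).

Thinning is not exactly equivariant under 90° rotation, so per-mask
features can shift slightly when a mask is rotated; the rotation-invariance
test therefore asserts tolerances in expectation over replicate masks
(orientation concentration within 0.05 on average).

## Texture features

Histogram moments are population moments of the raw intensities; energy
Σp² and entropy −Σp log₂p use a 256-bin histogram over the bit-depth range
(observed range for float images). Zero variance sets skewness and
kurtosis to 0 by convention.

Co-occurrence matrices are built on a uniform 16-level quantization of the
observed min–max range (quantization is therefore invariant to adding a
constant), symmetric and normalized, for displacements {1..5} px and
directions {0°, 45°, 90°, 135°} with the pixel-offset convention
(row, col) = (round(d sin θ), round(d cos θ)). Contrast, correlation,
energy and homogeneity are computed from the matrix directly; zero marginal
variance sets correlation to 0. The quantization level count is exposed
because oracle fixtures (e.g. a binary checkerboard with "one level"
differences) are only meaningful when the quantization preserves their
levels.

The Gabor bank uses frequencies {0.05, 0.1, 0.2, 0.4} cycles/px, six
orientations in 30° steps, and one-octave bandwidth. The image mean is
subtracted before filtering, making the effective filters DC-free (a
constant image responds zero). Convolution is FFT-based on a
symmetrically padded image and is exactly equal (to ~1e-16) to spatial
convolution with reflected boundaries.

The 142-name registry is fixed and ordered (8 morphological + 6 histogram
+ 80 GLCM + 48 Gabor); the split of the 134 texture features among the
three families is a design choice of this package, generated from the
displacement/direction/frequency grids above, and cohort tables address
features positionally as `tcmf_1..tcmf_142`. Texture is computed on the raw
ROI by default; masking to collagen pixels is a config toggle.

## Cohort simulator

Disease-free survival follows a Weibull proportional-hazards model,
S(t|x) = exp(−(t/λ)^k e^η) with η = β·x, so the hazard ratio between two
patients with linear predictors differing by Δ is exactly e^Δ. Defaults:
shape k = 1.5, scale λ = 91 months (baseline median ≈ 71 months, matching
the follow-up scale of the cohorts this emulates), administrative horizon
120 months, overall censored fraction 0.70, cohort split 355:334:253, and
clinical covariates drawn from the marginal frequencies of the emulated
study population. The exponential censoring rate is calibrated
deterministically: the expected event fraction under rate ρ is computed by
trapezoid quadrature of ∫₀^τ f_i(t)e^{−ρt}dt averaged over the drawn η_i,
and ρ is root-found with Brent's method — no Monte-Carlo tuning. Feature
names in β resolve to architecture indicators (Bernoulli), clinical
indicator contrasts (`column:level`), or standard-normal latents; the true
η is stored with every patient for oracle checks.

The image-backed cohort assigns each patient one archetype, gives the
archetypes log-hazards {+1: perpendicular, chaotic, dense; −1: curved,
parallel, sparse; 0: reticular, aligned}, renders 2–4 ROIs per patient
(scaled down from the 7–20 regions of the emulated protocol) and averages
their extracted features. Architecture indicator columns are the one-hot of
the assigned archetype, mirroring what visually assigned pattern labels
represent.

## Score models

All Cox partial likelihoods use the Efron tie correction. The LASSO path
is fit with the coordinate-descent elastic-net solver
(scikit-survival's Coxnet, l1_ratio = 1, 60 penalties down to 1% of the
maximal one); the penalty is chosen by k-fold cross-validated partial
likelihood using the Verweij–van Houwelingen contribution
ll(β; all) − ll(β; train), with folds stratified by the event indicator and
seeded. The default rule is one-standard-error (the largest penalty within
one SE of the optimum; `min` is available and is what the analysis scripts
use, since the simulated cohorts are small and the 1-SE rule is then very
conservative). Features must be standardized beforehand; the fitter does
not rescale. The ridge architecture score keeps all eight indicator
coefficients, with the L2 strength chosen on a log grid by the same CV
criterion. The clinical score is an unpenalized Cox fit over indicator
contrasts whose reference levels are the first-listed category of each
covariate (age ≤ 50, luminal A, T ≤ 2 cm, N0, stage I, G1, therapy = no).
Combined scores use the component scores' multivariate Cox coefficients as
weights; near-collinear components trigger a condition-number warning.
Models serialize to JSON at full precision with a format version.

## Evaluation estimators

The horizon ROC is cumulative/dynamic with IPCW: cases are events by t,
controls survive past t, cases are weighted 1/G(T⁻) and controls 1/G(t)
where G is the Kaplan–Meier estimate of the censoring distribution. The
implementation agrees with an independent estimator of the same quantity
to numerical precision (cross-checked in the tests, never substituted).
The Youden cutoff maximizes weighted sensitivity + specificity − 1 over
observed scores, breaking ties toward the lower cutoff; high risk is
score ≥ cutoff, and the cutoff is meant to be frozen on the training
cohort. AUC confidence intervals are patient-level percentile bootstrap
(default 1000 replicates, seeded; the analysis drivers use 200 to keep
runtimes short). iAUC weights AUC(t) by the Kaplan–Meier increments of the
event-time distribution over the grid, normalized (a Riemann sum against
the estimated event density). Harrell's C counts usable pairs (tᵢ < tⱼ,
eventᵢ = 1) with score ties as ½. Univariate Cox p-values are
likelihood-ratio against the null model; multivariate p-values drop one
covariate at a time; confidence intervals are Wald. No multiple-testing
correction is applied anywhere — reported p-values are raw.

The nomogram assigns points proportional to |β × covariate range|,
rescaled so the widest covariate spans 100; total points map to survival
through the Breslow baseline. Calibration compares mean predicted S(60)
with the KM-observed value in four predicted-risk quantile bins,
bootstrap-resampled (default 200). The score-to-survival curve is
S(60|s) = S₀(60)^exp(βs) from a univariate Cox fit, strictly monotone when
β ≠ 0.

## Problem sizes

The test suite and the acceptance script use: 128-px ROIs (1.17 µm/px) for
image-backed cohorts of 400 patients with 2–4 ROIs each; 50 replicate
cohorts of n = 500 for the planted-feature recovery study; n = 2000 for
null-score calibration and combined-weight recovery; n = 1000 for the
two-group hazard-ratio check. These sizes were chosen so each study is
informative while the whole pipeline remains cheap to re-run end to end.

## What the synthetic data does and does not show

The simulator produces fibers with known geometry, controlled overlap, and
simple noise; it does not emulate out-of-focus light, intensity
heterogeneity along a fiber, curvelet-scale wavyness, tissue autofluorescence
bleed-through, or the spatial correlation between neighboring ROIs of one
section. Passing tests therefore demonstrate that the estimators and the
extraction pipeline are correct and self-consistent on images whose truth
is known — not that the particular feature values transfer to real tissue.
Two known extraction biases are documented by the tests rather than hidden:
traced fiber counts exceed the generating count when fibers cross (crossing
fibers are cut at junctions unless the continuation rule rejoins them), and
extracted straightness is biased toward 1 for curved, crossing fibers
because fragments are straighter than their parents; ground-truth-level
orderings are asserted on the generating specs instead.
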