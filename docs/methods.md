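# Methods

This note documents the models, the synthetic-data design, the parameter
choices and their rationale, and the known limitations of `canopyspec`.

## Scope and data model

The pipeline analyzes VNIR hypercubes (height × width × 194 bands). Two
wavelength grids are built in: the synthetic default (194 evenly spaced
centers, 511–900 nm) and the Senop HSC-2 instrument grid. The instrument's
published band lists are reproduced exactly by
`round(linspace(510, 900, 194), 1)`, so the constant is generated rather
than transcribed; a regression test checks every published SPA wavelength
against it. Bands are always addressed by wavelength (nearest band center,
ties to the lower wavelength), never by vendor band index, because vendor
indices are not monotone in wavelength.

## Synthetic scenes and spectra

No public data accompanies the original greenhouse study, so the
generator in `canopyspec.synth` is a first-class, tested component that
defines the study conditions for every downstream test.

**Canopy endmember.** Reflectance is a sum of interpretable parts: a 0.05
visible floor; a Gaussian green bump at 550 nm; a chlorophyll absorption
dip at 670 nm (depth `pigment_depth`); a logistic red edge centered at
715 nm (width 10 nm) rising to a 0.45 NIR plateau that rolls off by 50%
from 800 to 900 nm (leaf water tail); and Gaussian water-overtone
absorptions at 742 and 842 nm (σ = 6 and 7 nm). Severity acts through
five parameters: `vis_gain` multiplies the spectrum at ≤ 700 nm (ramping
out by 740 nm, so reflectance at 670 nm is *exactly*
`vis_gain ×` control), `nir_loss` multiplies the plateau, the red edge
blue-shifts slightly, and the pigment and water dips grow shallower. The
pigment-dip collapse matters: a pure multiplicative visible lift would
scale MCARI *up* with stress, whereas pigment loss flattening the
670/700 nm contrast is what drives all four indices down monotonically,
as observed in stressed canopies.

**Default severity profiles.** control (1.0, 1.0, 0, 0.050, 0.035),
early (1.25, 0.92, −1 nm, 0.040, 0.026), severe (1.60, 0.75, −2 nm,
0.035, 0.018) for (vis_gain, nir_loss, red-edge shift, water depth,
pigment depth). Early is deliberately close to control — the hard
boundary in practice — while severe is well separated; the extreme pair
should essentially never be confused.

**Background.** Dry soil/bench: 0.26 visible reflectance with a +0.02
tilt, rising to ~0.63 above 800 nm. The background is brighter than
vegetation in the red and beyond ~840 nm but darker on the NIR plateau;
after per-channel min–max rescaling of the 679.7/790.9/871.7 nm
composite, plant pixels land in the published HSV segmentation windows
(hue ≈ 1/3) and soil in the magenta range, which is the geometry the
fixed thresholds assume.

**Distortions.** Scenes add per-pixel affine scatter (slope 0.98–1.02,
offset ±0.005) and Gaussian noise (SD 0.005 reflectance) — modest, since
pixels of one acquisition share illumination. Spectra *tables* emulate
ROI spectra: per-row scatter is strong (slope 0.8–1.2, offset ±0.05) so
MSC/SNV demonstrably change model inputs, while noise is SD 0.004
because a table row stands for the mean of a ~3×3-pixel ROI patch of
0.01-noise pixels. The raw-frame forward model is
`raw = dark + R · (white − dark)` with noise-free references, so
calibration inverts it to machine precision when noise and scatter are
disabled — the basis of the exactness tests.

**What the generator does not emulate.** Radiative-transfer realism
(PROSPECT/SAIL), 3-D canopy geometry and self-shadowing, mixed
soil/vegetation pixels, sensor quantization (DNs stay float so the
forward/inverse identity is exact), temporal drift, and biotic stress.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the assumed statistical structure, not field performance.

## Preprocessing

All operators are row-independent, so one fitted chain serves tables and
flattened cube pixels identically (this is asserted, and chemical maps
refuse cubes whose provenance differs from the model's). SNV uses the
sample (n−1) standard deviation. MSC freezes its reference — the mean
calibration spectrum — at fit time and reuses it for validation, test
and cube pixels to avoid leakage. Savitzky–Golay defaults to window 11,
polyorder 2 for smoothing and polyorder 3 for second derivatives
(derivative in per-band-index units); edges use the polynomial boundary
fits, keeping low-degree polynomials exact everywhere. PCA is
mean-centered only, no scaling.

## Splitting and models

Stratified 60/20/20 with largest-remainder rounding per category, seeded
shuffle; remainder ties go to calibration first then validation (e.g.
6558 → 3935/1312/1311). Hyperparameters are tuned by stratified 5-fold
CV on calibration only; the validation set drives latent-variable and
band selection; the test set is untouched until evaluation.

**PLS-DA** regresses a one-hot class block on centered spectra (no
scaling) and exports flat affine coefficients: `scores = X·β + β₀` with
`β₀ = ȳ − x̄·β`, so the same β applies pixel-wise in chemical imaging.
Latent variables are chosen on validation accuracy among 1–15 with 10
preferred on ties (the conventional choice when accuracy plateaus).
Class = arg-max score; a winning score above +0.5 flags the call as
confident, and the same 0.5 threshold separates "uncertain" pixels in
maps. **LDA** uses the pooled within-class covariance shrunk toward
`(tr Σ/p)·I`, λ ∈ {0, 0.01, 0.1, 0.3, 0.5} (singular grid points are
skipped); its reported scores are softmax posteriors of the
discriminants, because the raw δ share an x-dependent term that cancels
in arg-max but degrades one-vs-rest AUC. **SVM** is one RBF binary
machine per category (one-vs-rest), C ∈ {0.1, 1, 10, 100} and
γ ∈ (1/(p·var)) × {0.1, 1, 10}; support vectors, dual coefficients and
biases are exported so decisions can be recomputed as explicit kernel
sums. Metrics come from the confusion matrix (accuracy = trace/total;
macro precision/recall/F1, weighted variants available; never-predicted
categories get precision 0 with a flag) plus macro one-vs-rest AUC.

## SPA band selection

Chains are built by successive orthogonal projections on
calibration-centered columns; every (start band, subset size) candidate
is scored by the validation accuracy of a 10-LV (rank-limited) PLS-DA on
those bands, ties to smaller size then lower start. Two deliberate
choices:

* **Centering only, no unit-variance scaling.** Scaling columns to unit
  variance makes noise-dominated bands (where classes coincide) look
  maximally "orthogonal", and chains then collect runs of adjacent
  uninformative wavelengths; with centering alone the projections follow
  real variance and land on red-edge, water-band and visible features.
  A `scale=True` flag restores the scaled variant.
* **Default size window 8–32** (the practical compression range for this
  kind of instrument, which reports 21–32 retained bands from 194), and
  an optional evenly spaced subsample of start bands for speed; the
  library default searches all starts.

## Chemical maps

A masked reflectance cube is preprocessed with the model's own frozen
chain, restricted to the model's bands, and multiplied by β pixel-wise.
The map and the classifier are the same computation, so agreement with
`predict_plsda` on the extracted pixel matrix is bit-exact. Labels use
arg-max with the 0.5 confidence threshold; fractions (including
"uncertain") sum to 1 over the foreground. Rendering maps the arg-max
severity rank through viridis (blue = healthy → yellow/green = severe),
black background, gray uncertain pixels, with colormap and scaling in a
JSON sidecar; identical maps produce byte-identical files.

## Pipeline and problem sizes

`run_pipeline` executes simulate → calibrate → segment → preprocess →
indices/ANOVA → SPA → train → evaluate → map, embedding a hash of the
analysis configuration (output location excluded) in every artifact.
Stages re-run on each invocation; no caching layer is included because a
desk-scale run finishes in seconds. Default problem sizes — 600 spectra
(200 per category), 96×96 scenes, 24 SPA starts — were chosen so a full
run and the 10-seed recovery study complete in well under a minute and a
few minutes respectively on one CPU while keeping per-category test sets
large enough (n = 40) for stable accuracy estimates.

## Numerical choices and degenerate inputs

Reflectance clips at 1.5 (configurable) to tolerate super-white pixels
against a ~99% reference. Calibration raises, naming the first offending
pixel/band, when white ≤ dark anywhere. Zero-variance rows (SNV),
near-zero MSC slopes (|b| < 1e−8), degenerate normalization rows and
empty designs raise with the offending row named; empty segmentation
masks warn instead of raising so batch pipelines can report failures.
Duncan's test uses studentized-range critical values at the protection
level 1 − (1−α)^(p−1) with the harmonic mean of group sizes, and a
step-down rule so a non-significant span protects all sub-spans — which
guarantees letter groups form contiguous runs over the ordered means.
RDVI is implemented with the √(NIR+Red) denominator; a
`rdvi_as_printed` flag reproduces the typographic variant that
duplicates NDVI, whose published values cannot disambiguate the formula.

## Known limitations

* Synthetic severity classes are cleanly parameterized; real transitional
  physiology is messier, so absolute accuracies here exceed what mixed
  field pixels would allow.
* MCARI is sensitive to additive offsets (it is ratio-based); under the
  strong table-level scatter its per-sample variance is large until
  scatter correction is applied.
* The HSV segmentation thresholds are tied to the pseudo-color band
  choice and a soil-like background; other backgrounds need re-tuned
  windows.
* The ENVI reader supports the package's own band-sequential layout
  (plus multi-page TIFF), not every vendor dialect.
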