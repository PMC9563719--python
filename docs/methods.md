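# Methods

This note records the modelling choices behind `starchspec`: what each stage
assumes, which knobs matter, what the synthetic data do and do not emulate,
and where the design was genuinely open.

## Data model

A sample is a hyperspectral reflectance cube (rows × cols × bands) bound to a
strictly increasing wavelength grid; the default grid has 428 bands evenly
spanning 382–1004 nm. Cubes are exchanged as ENVI header/binary pairs (BIL,
BIP or BSQ interleave) or NPZ containers and always held in memory in
rows × cols × bands order. Reflectance calibration uses the two-point formula
R = (I_raw − I_dark)/(I_white − I_dark); elements where the white and dark
references coincide (dead pixels) are zeroed and counted rather than raised
on, since real reference cubes contain them.

## Spectral block

The per-sample spectrum is the arithmetic per-band mean over a fixed,
axis-aligned ROI (default 100 × 100 px, centred; 0-based half-open indexing,
start = ⌊(dim − size)/2⌋). There is no tuber segmentation: the ROI is assumed
to lie fully on the object. SNV standardises each spectrum to zero mean and
unit standard deviation across bands using the n−1 (sample) denominator — the
dominant chemometrics convention; switching to the population denominator is
a one-line change in `spectra._snv_matrix`. SNV removes exactly the
per-spectrum affine scatter component (a·x + b), which is also precisely the
scatter the generator plants.

## Texture block

PCA is computed **per sample** on that sample's own ROI pixels (pixels =
observations, bands = variables, mean-centred, Gram-matrix eigensolve).
Cross-sample comparability of score signs is restored by a deterministic
convention: the largest-magnitude element of every loading vector is made
positive. The alternative — one PCA pooled over all samples' pixels — would
give globally comparable scores but a different (and heavier) workflow; the
per-image transform matches how imaging software treats each cube
independently, and the run log records the choice.

Score images are quantized by linear min–max mapping to 64 gray levels
(⌊(x − min)/(max − min)·L⌋, max folded to L−1, constant image → level 0).
64 levels is a common GLCM default balancing co-occurrence sparsity against
discriminability. GLCMs are accumulated at distance 1 in four directions
with offsets (rows increasing downward) 0° → (0,+1), 45° → (−1,+1),
90° → (−1,0), 135° → (−1,−1), counted in both pair orders (symmetric) and
normalized to sum 1. Four statistics per direction are averaged over
directions:

* contrast = Σ (i−j)² pᵢⱼ
* correlation = Σ (i−μ)(j−μ) pᵢⱼ / σ² (symmetric GLCM: marginals coincide);
  defined as 0 when σ² = 0 so constant images propagate no NaNs
* entropy = −Σ pᵢⱼ log₂ pᵢⱼ (bits; base only rescales, and correlation-based
  selection is scale-free)
* uniformity = Σ pᵢⱼ² (angular second moment)

With three PC images this gives the 12-feature vector, named
`{feature}_PC{k}` in the order correlation, contrast, entropy, uniformity
per PC block.

## Variable selection

**CARS** (spectral block, SNV-treated spectra, calibration samples only).
Hyperparameters follow the method's canonical defaults — N = 50 runs, 80%
Monte-Carlo row sampling, ≤ 10 latent variables, 5-fold RMSECV — all exposed
in `CARSConfig`. The retention schedule is the exponentially decreasing
function r_i = a·e^(−k·i) pinned by r₁ = 1 and r_N = 2/p. In this
implementation the retained set at run i is exactly the top ⌈r_i·p⌉
variables by normalised |b|-weight (floored at 2), with the adaptive
reweighted draw performed as weighted sampling **without** replacement of
that same count — i.e. the schedule is deterministic given the Monte-Carlo
weights, and run-to-run randomness enters only through the row subsample.
This keeps the retained-count sequence exactly on the EDF schedule, which
the with-replacement-and-deduplicate variant would not.

**Texture screen.** Plain Pearson correlation of each of the 12 features
with starch on the calibration set; features with |r| strictly above 0.3 are
kept; constant columns get r = 0. Selection on the calibration set only
avoids leaking prediction-set responses into model building.

**Fusion.** Low-level: column concatenation of the full SNV-spectral and
texture blocks (428 + 12 = 440). Mid-level: CARS-selected wavelengths then
correlation-selected texture features. Because spectral and texture columns
live on incommensurate scales, all model fits autoscale predictors
(calibration statistics); the response is centred only.

## Regression and evaluation

PLS1 by NIPALS with sequential deflation; nested coefficient vectors
B_k = W_k(P_kᵀW_k)^{-1}q_k are stored for all k up to the requested count, so
cross-validation curves cost one fit per fold. The LV count (≤ 15) is chosen
by 5-fold cross-validation — folds are contiguous blocks of a seeded
shuffle — with the **one-standard-error rule**: the smallest count whose
cross-validated MSE is within one standard error of the minimum. A strict
argmin was tried first and rejected: past the elbow the RMSECV curve is
essentially flat, and the argmin wanders over 4–8 components with no
predictive benefit, defeating the parsimony the tie-break is supposed to
provide.

The calibration/prediction split is the deterministic rank-order rule: sort
by starch (ties by input order), middle of every consecutive triplet →
prediction set, leftovers → calibration; 96 samples give 64/32 and the
prediction range is strictly inside the calibration range by construction.
Models are scored with Rc/Rp, RMSEC/RMSEP and RPD = SD(y_pred, n−1)/RMSEP
(reported +inf for a perfect model); the RPD·RMSEP = SD identity is asserted
in tests to 1e-12.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the pipeline needs:

* **Reference values.** Two varieties, 68 + 28 samples, starch from normals
  truncated (by exact rejection sampling) to each variety's min/max — mean
  10.23, SD 2.95 on [1.77, 18.31] and mean 18.96, SD 1.29 on [17.01, 22.81]
  g/100 g.
* **Spectra.** Baseline 0.6 reflectance minus Gaussian dips (σ = 15 nm) at
  410, 680 and 980 nm. Dip depth at peak c is gain·scale_c·(offset_c +
  starch) with per-peak scales (0.010, 0.006, 0.004) and offsets (2, 12, 30):
  every dip deepens with starch, but at different relative rates, so the dip
  **ratios** carry starch information that survives SNV's per-spectrum
  rescaling. (An early single-response variant made all dips proportional to
  one affine function of starch; SNV then normalised the signal away
  entirely — a useful reminder that rank-1 spectral variation is invisible
  after scatter correction.) Per-sample multiplicative/additive scatter
  (SDs 0.08 / 0.03) is planted for SNV to remove, plus i.i.d. band noise
  (SD 0.004).
* **Texture.** Each pixel's spectrum is the sample spectrum modulated by two
  spatial fields — one scaling brightness, one perturbing the dip-shape
  direction (so PC2 inherits texture signal) — built from Gaussian-filtered
  white noise whose correlation length shrinks with starch
  (6 px − 0.18 px per g/100 g, floored at 1.2) plus sparse ±5σ impulse
  speckle whose density falls from 10% to zero at 25 g/100 g. The impulses
  stretch the min–max quantization range, concentrating the gray-level
  histogram (high uniformity) while being spatially incoherent (low GLCM
  correlation); as starch rises the field turns smooth and spread, so
  uniformity falls and GLCM correlation rises — the sign pattern the texture
  screen expects. A per-sample jitter (SD 5 g/100 g) on the texture-driving
  starch value keeps feature–starch correlations moderate (|r| ≈ 0.6–0.8)
  instead of deterministic; the resulting texture-only model lands at
  RPD ≈ 1.4–2.0, a realistic "weak single block".

Not emulated: instrument optics, specular glare, tuber shape/background
(hence no segmentation), wavelength-dependent noise, and any real
biochemical relationship between surface texture and starch. Passing tests
therefore show that the pipeline recovers structure *of the planted kind*,
not that these models would reach the same accuracy on real tubers; in
particular the synthetic spectra are cleaner than instrument spectra, so
absolute Rp/RPD values run higher than one should expect in practice.

## Numerical choices and degenerate inputs

* PCA via scikit-learn's Gram-matrix ("covariance_eigh") solver: exact for
  these tall-thin pixel matrices and much faster than a dense SVD at 3
  components; verified in tests against a brute-force covariance
  eigendecomposition.
* NIPALS stops early (with a warning) if the residual covariance vanishes;
  cross-validation reuses the largest available component count upward.
* Zero-variance predictor columns get unit scale (they contribute nothing
  after centring); zero-variance y is an error everywhere.
* Constant spectra are rejected by SNV with the offending sample named;
  constant images quantize to level 0 and yield the degenerate GLCM
  (uniformity 1, others 0).
* Cubes are float32 end to end in the generator (a 96 × 120 × 120 × 428
  dataset streams one cube at a time through feature extraction); all
  downstream tables are float64.
* Determinism: every randomised step (generator, CARS row sampling, CV fold
  shuffle) derives from one master seed; dataset cubes use seed + sample
  index so single samples are reproducible in isolation.

## Problem sizes used by the test suite

Unit and property tests run on small fixtures (8 × 8 to 12 × 12 images,
20–60 sample regression problems). End-to-end statistical checks use the
full default design — five seeds of the 96-cube dataset for the
fusion-beats-texture comparison, 20 seeds of a 60 × 100 planted-signal
problem for CARS recovery — and a scaled-down 24-sample, 120-band dataset
for the byte-identical determinism check, whose property does not depend on
problem size. The whole suite runs in about two minutes on one CPU.

## Known limitations

* Per-sample PCA means texture features from different samples live in
  slightly different score spaces; the sign convention restores orientation
  but not scale. A pooled-PCA mode would remove this at the cost of a second
  pass over all cubes.
* CARS here is the deterministic-schedule variant described above; the
  stochastic with-replacement resampling of the original formulation can
  escape locally-greedy eliminations in ways this variant cannot.
* The ROI is fixed and centred; on real images it must be placed on the
  tuber by the operator or an upstream segmentation step.
* Wavelength selection quality is reported only through RMSECV; no stability
  analysis across Monte-Carlo repetitions is implemented.
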