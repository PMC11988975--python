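# Methods

## The measurement and its data representation

The instrument being modelled is a smartphone in a dark chamber, screen
parallel to a pressed powder pellet at a fixed standoff. The screen steps
through a colour gradient from purple to red while the front camera records
a ~5 s video; decoded videos yield 177–179 frames, of which the first 177
are kept so all acquisitions align. A fixed 120×120-pixel region of
interest (ROI) is cropped from the frame centre — the geometry is fixed, so
no segmentation is attempted — and the mean R, G and B colour level of the
ROI in each frame is concatenated as R block | G block | B block into a
length-3F vector (531 variables at F = 177), each entry in [0, 255]. Means
are kept real-valued; re-quantizing to integer levels would discard
sub-level class separation.

The screen gradient is realised as a linear hue sweep 270° → 0° in HSV at
full saturation and value, quantized to 8-bit RGB. The endpoints are fixed
by the physical design (purple start, pure red end); the linear sweep is
the simplest monotone, reproducible interpolation between them.

## Forward simulator

The simulator exists so the full pipeline — ingest, feature extraction,
model fitting and evaluation — is testable without recorded video. Per
frame f and channel c the forward model is

    pixel = clamp(round(screen[f, c] · reflectance_c(f) + ε), 0, 255),

with ε i.i.d. Gaussian pixel noise (default sd 2.0 colour levels, a modest
sensor read-noise scale). Surface reflectance per channel is a smooth
curve over normalised frame position t ∈ [0, 1]: a constant offset plus
Gaussian bumps, with offsets/amplitudes non-negative and summing ≤ 1 so
the curve stays in [0, 1]. Smooth frame-dependent curves (rather than one
scalar per channel) let classes separate in mid-gradient variables, as the
real data do.

Within-class variability is a multiplicative jitter on each offset and
amplitude, scale 1 + 0.02·z (2% relative, the default), drawn per sample
from a per-sample child generator of the dataset seed, so datasets are
bit-reproducible and independent of iteration order.

Adulteration acts by affine mixing of reflectance curves:
mix(base, adulterant, c) evaluates to (1−c)·base + c·adulterant at every
frame and channel. This is the simplest model consistent with monotone
level trends in the features, and it makes adulteration levels linearly
decodable at zero noise — the basis of the level-recovery checks.

### Study design

Five tasks on whey protein concentrate (WPC): tasks 1–3 share one design
of 15 brands × 12 replicates = 180 samples, labelled with brand and the
certified fat (1.3–10.1 g/100 g) and energy (1607–1776 kJ/100 g) values
embedded in `synth.py`; task 4 is 3 adulterants × 10 levels
(0.05–0.50 step 0.05) × 5 replicates = 150, all in a B1 base; task 5 is
the milk-powder series, 10 levels × 5 replicates plus 5 pure (level-0) B1
samples = 55. The 55 = 50 + 5 composition of task 5 is a design inference;
the 5 extras are taken to be unadulterated base samples.

### Default class profiles

Each brand's reflectance gets (i) a unique Gaussian bump centre in the
green channel (centres 0.08–0.864, width 0.055), which separates all 15
brands by construction; (ii) a red-channel amplitude scaling linearly with
certified fat; (iii) a blue-channel amplitude scaling linearly with
certified energy. The fat/energy links are imposed as a documented testing
convenience — they make the regression tasks well-posed in simulation,
not a claim that certified composition is optically recoverable from real
pellets. Adulterant profiles make milk powder clearly distinct (yellowish:
low blue) while maltodextrin and wheat flour are both near-white and
deliberately closer to each other, mirroring their visual similarity.

What the simulator does NOT emulate: MP4 compression, lens vignetting,
ambient light leakage, exposure drift, spatial texture within the ROI
(pixels are i.i.d. around a frame-constant mean), or device-to-device
variation. Passing tests therefore demonstrate the correctness of the
pipeline and models under the stated forward model, not field performance
on recorded video.

## Models

**PLSR** uses NIPALS with deflation of X only, fitted one response column
at a time (PLS1): w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, X ← X − tpᵀ.
Successive scores are orthogonal; components are nested, so one fit at
A_max yields predictions at every smaller A (used during cross-validation).
Coefficients are B = W(PᵀW)⁻¹q; at full rank this reproduces ordinary
least squares, the cross-check used in the tests. Predictors and responses
are column-mean-centred inside the fit. If the predictor rank is exhausted
early, extraction stops and the model silently carries fewer components.

**PLS-DA** regresses the one-hot indicator matrix with the same PLS core
and predicts by argmax over the predicted dummy columns; ties break to the
lowest class index for determinism.

**K-ELM** solves (I/C + K)α = T by Cholesky factorisation (the system is
symmetric positive definite for any finite C > 0; no explicit inverse).
The kernel is K(u, v) = exp(−‖u−v‖²/σ) with the width σ — not a rate
γ = 1/σ — searched over 2¹..2¹⁰ jointly with C (100 candidates, integer
exponents). With min-max-normalised 531-variable spectra, squared
distances between samples are O(1–10); a rate-form kernel exp(−γd²) with
γ ≥ 2 would collapse K to near-identity everywhere on that grid, so the
width parameterisation is the one under which the stated grid is
meaningful (it is also the form of the original kernel-ELM formulation).

## Evaluation protocol

- **Split**: 2:1 train/test, ⌈2n/3⌉ training rows, stratified — by class
  for classification, by brand for the fat/energy tasks, by level for the
  adulteration series. Plain random splitting would risk losing one of 15
  classes (12 replicates each) from the test set. Per-stratum training
  counts are ⌊2nₖ/3⌋ with the remainder distributed by largest fractional
  part, never emptying a stratum's test half.
- **Selection**: 10-fold CV on the training set (stratified folds for
  classification), pooled out-of-fold predictions scored by RMSE
  (regression) or accuracy (classification); ties go to the first
  candidate in grid order. Pooled rather than fold-averaged metrics keep
  the criterion well-defined when folds are small.
- **Normalization**: per-variable min-max fitted on training rows only and
  refitted inside each CV fold on that fold's fit-part, so no held-out
  statistic leaks into any fit. Zero-range variables map to 0; test values
  are not clipped to [0, 1]. `paper_compat=True` instead normalises once
  over all samples before splitting — the common order in applied work,
  kept as an explicit, clearly-labelled option.
- **Metrics**: RMSE, MAE, R² = 1 − SS_res/SS_tot with SS_tot about the
  evaluated set's own mean (so R²_CV and R²_P are each self-referenced);
  accuracy with a fixed-class-order confusion matrix. R² on a constant
  truth raises an error rather than returning a sentinel.

All randomness in a run (split, folds) derives from one seed; reports are
serialised with sorted keys and no timestamps, so reruns are
byte-identical.

## Numerical choices and degenerate inputs

NIPALS stops on ‖Xᵀy‖ < 1e−12 (rank exhaustion); zero-variance responses
are rejected. The RBF distance matrix is clipped at 0 against roundoff so
the diagonal is exactly 1. Mixing levels outside [0, 1], out-of-bounds
ROIs, short frame stacks (error names the deficit), single-class PLS-DA,
non-positive C/σ, and transform-before-fit are all rejected with typed
errors.

## Problem sizes in tests and the acceptance script

Zero pixel noise makes every ROI pixel identical, so the ROI size is
irrelevant to zero-noise spectra; noise-free end-to-end checks use small
ROIs purely for speed. Repeated noisy end-to-end runs (ten-seed level
recovery, the noise ladder) use 12–16-pixel ROIs while keeping F = 177,
the full task designs and the default noise model; at roi 16 the
pixel-noise contribution to a channel mean is sd/16, which preserves the
noise regime qualitatively while keeping a full ladder under a minute.

The pixel-noise ladder deliberately sets jitter to 0 — pixel noise is the
variable being swept, and jitter realisations (drawn before pixel noise
from the same per-sample stream) would otherwise add shared dither — and
uses sd ∈ {0, 120, 240} at roi 12, spaced so the expected accuracy drops
dominate ten-seed sampling error; at sd = 0 the run is fully deterministic
with accuracy 1.0.

## Known limitations

- PLS1-per-column PLS-DA ignores response covariance between dummy
  columns; with ≥ 15 classes a PLS2 variant can differ slightly.
- The simulator's class separability is generous by construction;
  simulated accuracies say nothing quantitative about recorded-video
  accuracy on real WPC.
- No preprocessing beyond min-max (no SNV/derivatives) and no video
  decoding: MP4s must be split into frame directories by an external
  extractor before `svispec convert`.
- K-ELM stores all training rows; fine at n ≤ 200, not intended for large
  datasets.
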