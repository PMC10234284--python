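# Methods

This note documents the models, parameter choices, and numerical conventions
behind `dfoct`, and what the synthetic phantoms do and do not establish about
real tissue data.

## Spectral reconstruction

Per-pixel PSDs use Welch's method: mean-removed segments of
`min(128, n_frames)` samples, Hann window, 50% overlap. The estimator is a
batched re-implementation (one FFT call over all pixels and segments via
`scipy.fft`) verified in the tests to agree with per-pixel
`scipy.signal.welch` to ~1e-16; the batching is purely for speed on full
fields of view. Each PSD is then L1-normalized; pixels with zero total power
are flagged rather than divided, and render as dark blue-grey
(hue 0.66, saturation 0).

*Bandwidth* is the spectral standard deviation (square root of the second
central moment) — the conventional scalar bandwidth; the mapping to
saturation is a single monotone-decreasing affine map, since only the net
direction (broader spectrum → lower saturation) is physically determined.
Hue and saturation use fixed physical ranges by default
(`f_min = 0`, `f_max = Nyquist`, `bw_max = Nyquist/2`) so that images are
comparable across acquisitions; a per-image 1–99% percentile stretch of the
mean-frequency axis is available as a display option.

The cumulative-sum value statistic uses non-overlapping windows of τ = 16
frames with stride τ; trailing frames beyond the last full window are
discarded. The statistic is exactly 1-homogeneous in signal amplitude and
zero on constant input. The `rgb` render display-stretches the value channel
at its own 1st/99th percentiles; `value_raw` (camera counts) is kept
untouched for quantitative use. Because any per-image stretch destroys
cross-image comparability, the pixel classifier consumes `hsv_raw`
(hue, saturation, raw value) instead of the display render — without this, a
field of view containing no cells would have its noise floor stretched to
full brightness and be misread as cellular.

Legacy band-RGB images sum the un-normalized PSD over 0–0.6 / 0.6–5.4 /
5.4–25 Hz; the band edges are fixed instrument constants. Display scales
each channel by its own 99th percentile; the raw band powers are preserved
in the image metadata.

## Phantoms

Cells are equal-area ellipses (radius ~ N(mean, sd), eccentricity uniform in
a configured range); fibers are line segments with axial von Mises
orientations (concentration κ; κ→0 is isotropic); fat is dark discs.
Overlaps resolve with priority fat > cell > fiber. Dynamics: each cell
carries one shared sum of five discrete Ornstein–Uhlenbeck walks
(`x_t = a x_{t−1} + σ√(1−a²) ε`, `a = exp(−1/(f_s τ_c))`), so the lag-1
autocorrelation of the noise-free cell signal is exactly `a`; every pixel
adds independent white camera noise. All randomness descends from one root
seed through `numpy.random.SeedSequence` spawning, so equal seeds give
bitwise-identical phantoms.

Default conditions (healthy → tumoral): cell density 400 → 1000 /mm²
(2.5×), mean radius 5 → 7.5 µm (1.5×), eccentricity range (0, 0.5) →
(0.3, 0.8), intracellular correlation time 0.15 → 0.05 s (tumor cells are
more motile, shifting spectral content up), dynamics amplitude 10 → 14
(counts), fiber coverage 0.12 → 0.08, fiber κ 4.0 → 0.2 (disorganization),
fat fraction 0.08 → 0.02, noise σ = 1. The desk-scale default field is
360 px (0.9 µm/px) and 256 frames at 150 Hz so a full single-ROI pipeline
runs in about two seconds; full-scale 1440 px / 1000 frames remains
configurable.

Multi-specimen datasets mirror the clinical labeling structure: healthy
specimens contain only healthy fields; tumoral specimens receive a
deterministic `round(0.7 · n_rois)` tumoral fields at random positions, the
rest healthy-looking. The sample diagnosis is inherited by every field (the
noisy "clinical" label), while the generating label is recorded as ground
truth. A deterministic count, rather than per-field Bernoulli draws, keeps
every tumoral specimen's tumoral majority — a property real resected tumors
have and on which the 0.5 normal-ratio rule depends; with Bernoulli draws a
specimen would be majority-healthy with ~8% probability and no classifier
could call it correctly.

**What phantoms do not emulate:** speckle statistics and coherence gating,
realistic collagen texture, carcinoma subtypes, intensity inhomogeneity,
imaging artifacts (folds, bubbles) and inter-patient variability. Passing
recovery tests therefore establishes the correctness and sensitivity of the
pipeline machinery, not clinical performance.

## Pixel classification

The iLastik-style interactive workflow is replaced by a documented
procedure: per channel and per scale σ ∈ {0.7, 1.6, 3.5, 7.0} px, the
feature bank holds Gaussian smoothing, Gaussian gradient magnitude,
Laplacian of Gaussian, and the leading structure-tensor and Hessian
eigenvalues (reflect padding; float32). A 100-tree random forest trains on
scribbles only; scribbles are auto-derived from phantom ground truth (class
masks eroded 2 px, ≤ 2000 pixels per class). Argmax ties resolve to the
lowest class index. The exact interactive feature set of the original
workflow is not recorded anywhere, so equivalence is functional, not
bitwise. Ground-truth-derived masks are drop-in substitutes for classifier
masks everywhere downstream, which lets feature tests isolate themselves
from classifier noise.

## Engineered features

The 44-slot schema (frozen, versioned):
cells 14 (count, density, mean/sd of equivalent diameter, eccentricity,
R, G, B intensity, intra-cell intensity sd) · mesoscale cells 7 (region
count, mean/sd of surface and eccentricity, count and fraction of cells
outside regions) · fibers 10 (count, density, mean/sd of area,
eccentricity, orientation, intensity) · mesoscale fibers 7 (region count,
mean/sd of area, eccentricity, intensity) · static cell-region intensity 2 ·
fat 4 (proportion, region count, mean/sd of region area).

Conventions: diameter = equivalent-circle diameter from area; density =
class pixels / total pixels; sd = population standard deviation (0 for a
single object); orientations are axial and summarized by circular mean/sd
with period 180°; absent measurements contribute 0. The mesoscale density
map is a square box filter (60 px) with zero padding computed by FFT
convolution; window sums are rounded to integers before division so
thresholding ("strictly above 0.05 / 0.1") is exact arithmetic. Fiber
intensity is read from the raw static image.

## SVM pipeline

Features are z-scored with training-fold statistics; folds are assigned at
specimen level (classes shuffled, dealt round-robin) so every fold's
diagnosis mix is within one specimen of the global proportions and no ROI of
a test specimen ever influences training statistics. The SVM is linear with
per-class cost multipliers (healthy errors × 3). The base regularization
constant defaults to **C = 0.05**: ROI training labels inherited from the
specimen diagnosis are partly wrong (healthy-looking fields inside tumoral
specimens), and with a weakly regularized fit those mislabeled points — which
sit deep inside the healthy feature cluster — drag the decision boundary into
the healthy side faster than the 3× cost can compensate (on the default
phantom cohort, grouped-CV specificity degrades from ~0.98 to ~0.62 as C
grows from 0.05 to 1). Strong regularization keeps the weighted class masses
in charge of the boundary. C is exposed for users whose labels are clean.

Diagonal NCA learns nonnegative per-feature weights by maximizing the
expected leave-one-out accuracy under the stochastic-neighbor rule with a
weighted-L1 distance and an L2 penalty; the penalty strength is picked on a
20-point logarithmic grid (10⁻³…1 relative to n) by held-out-fold expected
accuracy — in-sample selection would always prefer the unregularized,
overfit weighting. Selection keeps weights strictly above 0.05.

Specimen aggregation: normal-ROI ratio with a strict `> 0.5` comparison;
a tie resolves to tumoral, the safer clinical call. Tumoral is the positive
class in all metrics; AUC integrates the ROC by the trapezoidal rule.

## CNN

The numpy implementation (im2col convolutions, explicit backward passes) is
gradient-checked against central finite differences in the tests. He-uniform
initialization with a fixed seed replaces transfer learning: pretrained
weights are out of scope, so the full 13-conv profile exists chiefly for the
closed-form analytics (receptive fields 6/16/44/100/212; parameters
15,241,025 of which 526,337 in the GAP/FC-1024/sigmoid head), while training
experiments use a reduced profile ((1,8),(1,16),(1,32), FC-64) on 96-px
phantoms — sized so the desk-scale recovery experiment (250 fields, 10
specimens) trains in minutes on one CPU.

Training follows the clinical protocol exactly: class-weighted BCE (1.5
healthy / 0.75 tumoral, computed in logit space), SGD momentum 0.8,
lr 1e-4, batch 3, early stopping on validation loss (patience 100) or 100%
training accuracy, best-validation weights restored. Augmentation is pinned
at six variants per field: {no-op, 2–98%, 5–95% percentile stretch} ×
{identity, horizontal flip}; vertical flips are available via `flip_mode`.
Max-pool backward splits gradient evenly among tied maxima so the finite
difference check holds on ties.

Specimen aggregation uses the linear-interpolation 90th percentile of ROI
probabilities, strict `> 0.5`. Grad-CAM rectifies each layer's weighted
activation sum, upsamples the coarser map ×2 (nearest neighbor) per block
gap, sums, and rectifies again; the negative (healthy) target backpropagates
the complementary logit −z of the single sigmoid output.

## Problem sizes in tests

The recovery experiments run at deliberately reduced scale chosen as part of
the package design: 12 specimens × 11 fields (360 px, 256 frames) for the
SVM pipeline, evaluated with specimen-grouped 5-fold CV against the true
generating labels; 10 specimens × 25 fields (96 px) with a 200/50
specimen-grouped split and 40 training epochs for the CNN. Feature
extraction in the SVM recovery experiment runs from ground-truth masks (the
documented substitutability), while the random-forest segmentation chain is
validated separately by a held-out phantom IoU test.

## Known limitations

- Phantom realism is deliberately minimal (see above); clinical accuracy
  claims cannot be established here.
- The 44-feature inventory follows the documented measurement categories but
  the original ordering is not independently recorded; the schema is frozen
  and versioned to keep downstream models stable.
- The full-profile CNN is analytically complete but not trained in tests
  (no pretrained weights; CPU-scale budget).
- NCA fitting is O(n²p) per gradient step and intended for cohort-scale
  (hundreds of ROIs), not pixel-scale, problems.
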