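# Methods

## Data model and conventions

Multi-coil 2D Cartesian k-space is a complex tensor `(coil, kx, ky)`;
kx (readout) is always fully sampled, and uniform acceleration by R
retains the ky lines `{m0, m0+R, ...}` (1-based phase m0).  Full-grid
recovery is decomposed into R−1 independent subtasks: one model per line
offset m ∈ {1..R−1} predicts the lines shifted by m from the acquired
pattern.  Documented line-index math uses the conventional 1-based
TR(m) = {m, m+R, ...} notation; code is 0-based half-open.

All Fourier transforms are centered (DC at the matrix center) and
orthonormal in both directions, so Parseval's identity is exact and
energy checks are trivial.  The convention also makes k-space samples
periodic, which the reconstruction step exploits (below).

## Interpolation models

All convolutions act on the decimated acquired-line grid: a ky kernel
tap steps over consecutive acquired lines (spacing R in full-grid
units); kx runs at full resolution.  No layer has a bias.  The three
families:

- **GRAPPA**: one complex convolution `(nx_g, ny_g)` over all coils.
- **rRAKI**: a real 3-layer CNN on 2·Nc channels (real/imag
  concatenated) summed with a real linear short connection.  Default
  layers `[5,2,2Nc,32] → [1,1,32,8] → [3,2,8,2Nc]`, short connection
  `[5,2,2Nc,2Nc]`; activations (LeakyReLU, slope c) after layers 1 and 2
  only, following the three-layer RAKI convention.
- **crRAKI**: the complex counterpart with exact complex
  multiply-accumulate convolutions (kernel pairs Wr, Wi) and layers
  `[5,2,Nc,16] → [1,1,16,32] → [3,2,32,Nc]`, short connection
  `[1,1,Nc,Nc]`.

The complex activation is the *split* LeakyReLU (applied independently
to real and imaginary parts).  This is the unique choice that is exactly
the identity at c = 1, which the linear limit of the model family
requires; at c = 1 every family satisfies superposition to machine
precision, and the parameter-count arithmetic (2× per complex kernel)
makes crRAKI with the default layers (43,040 real parameters at Nc = 52)
more compact than the default [5,4] GRAPPA kernel (108,160).

Note one bookkeeping subtlety: the default crRAKI layer depths (16, 32)
are not half the default rRAKI real depths (32, 8); the two defaults are
stored verbatim per family, and the search grids enumerate depths
{16, 8, 4} in complex units ({32, 16, 8} real).

### Kernel geometry

Valid (no-padding) convolutions are used during calibration; training
targets are cropped to the intersection of the CNN-path and
short-connection output supports, so no border k-space is fabricated.
Output anchoring uses the per-layer offset `(k−1)//2` per axis: for an
even ky extent the predicted line sits between the two central taps.
The same anchoring is used in fitting and application, so the two cannot
disagree.

When a trained model is applied to a full scan, convolutions become
*circular* along both axes.  Because the DFT convention makes k-space
samples of a discrete image exactly periodic, periodic application is
not an approximation: in the bandlimited-coil regime it reproduces every
missing line, including at the array border, which is what lets the
exact-interpolation tests demand reconstruction errors at the 1e-3 level
and below.  Circular application requires Ny divisible by R and is
checked.

### Closed-form GRAPPA

`fit_grappa_tikhonov` assembles every sliding ACS source patch (ky taps
spaced R apart, all start phases) into a matrix A and solves
`(AᴴA + μI) w = AᴴB` per output coil with `μ = λ·trace(AᴴA)/n_cols`,
default λ = 1e-3.  The trace scaling makes λ dimensionless; λ = 0 gives
plain least squares.

## Training

The ACS is normalized by the global 2-norm over all samples and coils
(the scale is kept for de-normalization; undersampled data are brought
to the same scale before nonlinear models are applied).  The TVP
partition builds R pair sets — phase p contributes inputs TR(p)∩ACS and
targets shifted by m — of which R−1 train and the last (by default)
validates.  The loss is `MSE(pred, target) + λ·MSE(short, target)` with
complex MSE the mean squared modulus; λ = 0 and c = 1 define the linear
variants, λ = 1 and c = 0 the nonlinear ones.

Optimization is Adam (lr 1e-3 by default, at most 1000 epochs), one full
batch per pair set per epoch, implemented directly in numpy: im2col
convolutions with hand-derived adjoints, Wirtinger-calculus gradients
for complex kernels whose real and imaginary parts are independent real
parameters (verified against finite differences in the unit tests).
Weights initialize from zero-mean normals with std `sqrt(2/fan_in)` (He
initialization; for complex kernels the fan-in counts both components).

Early stopping: after each epoch the validation k-space MSE is recorded;
training stops when it has failed to improve on the running best for
more than `patience` (default 20) consecutive epochs, and the weights of
the best-validation epoch are returned.  Whether "increase" should be
read against the running best or the previous epoch is genuinely
ambiguous; the running-best reading matches the retained-best-epoch
semantics and is the default, with the alternative behind
`TrainConfig(monitor="previous")`.  Non-finite losses abort with a
diagnostic rather than silently returning garbage.

## Hyperparameter selection

`enumerate_grid` reproduces the published search spaces: 8 GRAPPA
kernels ([3,2], [5,2], [5,4], [5,5], [7,2], [7,4], [9,2], [9,4]) and 72
rRAKI/crRAKI combinations (first layer {[5,2],[5,4]} × depth-1 ×
depth-2 {16,8,4 complex} × third layer {[3,2],[3,4]} × short connection
{[5,2],[1,1]}).  `kfold_cv` runs K = R folds: each TVP phase serves once
as validation, every offset model is trained, and validation MSEs are
pooled by averaging over offsets into one sample per (fold, slice).
Training seeds derive from the configuration label, fold and offset
only, so results are independent of execution order and duplicate
slices contribute identical samples.

The best architecture is the arg-min of mean MSE (ties toward fewer
parameters).  The screening sentence in the source protocol is
internally inconsistent (rejecting "best is smaller" would *exclude* the
best-like configs); the statistically coherent reading is implemented —
configurations *not* significantly worse than the best (one-tailed Welch
test, p ≥ α) form the optimal set — and the raw p-values are exposed so
the other reading can be applied.  `linearity_ablation` sweeps
c ∈ {0, 0.01, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 1} × λ ∈ {0, 1} (18 rows)
through the same cross-validation.

## Metrics

NRMSE, NMAE and PSNR are computed over a mask (Otsu threshold on the
ground-truth magnitude, morphological closing, largest connected
component).  SSIM uses the standard 11×11 Gaussian window (σ = 1.5,
K1 = 0.01, K2 = 0.03, population statistics) with the data range taken
from the ground truth.  The blur score is the re-blur ratio metric:
compare the loss of neighboring-pixel variation after 9-tap directional
averaging; max of the two directions, 1 = maximally blurred.

COBRA/COBRAI: both magnitudes are normalized by the ground-truth
maximum; the residual map is their difference.  At every pixel the
Pearson correlation between the sliding `patch×patch` residual window
and the co-located ground-truth window is computed (stride 1, mirroring
dense SSIM; the stride is configurable since block-wise variants exist).
Boundary windows use the pixels they actually cover; windows with zero
variance in either operand score 0 (a flat residual carries no
structured artifact).  COBRAI is the mean absolute correlation over
patch centers inside the mask, guaranteed in [0, 1].  For residuals
independent of the anatomy the per-patch |r| concentrates around
`sqrt(2/(π·n))` with n = patch² (≈ 0.073 at 11×11; neighboring windows
are correlated, but the mean is unaffected), which the calibration tests
check within ±20%; structured ghosting at matched RMSE scores strictly
higher.

Method comparison follows the protocol: Shapiro–Wilk on the paired
differences, then a one-tailed paired t-test of "method a scores lower";
when normality is rejected the result is flagged and a one-sided
Wilcoxon signed-rank p-value is reported alongside (the fallback choice
is ours; the protocol is silent on it).  Identical score lists return
p = 0.5 by symmetry rather than the undefined 0/0 statistic.

## The simulator and what passing tests show

`simkit` emulates: piecewise-constant ellipse phantoms with per-tissue
R2* (0.005–0.05 /ms, i.e. T2* of 20–200 ms) and low-order polynomial
phase/off-resonance maps; smooth Gaussian-lobe coil sensitivities at
equally spaced angles with linear phase ramps; multi-echo GRE contrast
`magnitude·exp(−TE·R2*)·exp(i(phase + TE·Δω))`; iid circularly symmetric
complex Gaussian k-space noise; ACS extraction in integrated mode (same
contrast) or separated mode (different echo time, hence different
magnitude and phase).  Every generator is a pure function of its seed.

Two deliberately idealized regimes exist for testing:

- `make_coil_maps(mode="bandlimited")` confines coil spectra to a small
  box (with a boosted near-DC tap so the sum-of-squares never vanishes),
  the regime where an exact linear interpolation kernel exists;
- `make_texture_phantom` generates a full-support random-texture object
  with a flat spectrum.  With the smooth phantom, the calibration matrix
  has a wide spread of excited singular values (k-space dynamic range),
  and first-order training stalls far from the exact solution; the flat
  spectrum keeps the problem well conditioned on its row space so
  trained linear models actually reach the closed form.

The simulator does not model anatomy, Biot–Savart coil physics, gradient
timing, motion, or non-Cartesian/partial-Fourier sampling.  Passing
tests therefore demonstrate the correctness of the algorithms and the
direction of the contrast-generalization effect, not clinical image
quality on real scans.

## Problem sizes used by the test suite

All experiments run on 64×64 matrices: the oracle checks use 4
bandlimited coils at R = 2 with 24 ACS lines; the separated-mode
comparison uses 10 slices, 8 smooth coils, R = 4, 24 ACS lines, scan
echo 20 ms vs calibration echo 3 ms, k-space noise σ = 0.002, and the
published defaults for both architectures (crRAKI with c = 1, λ = 0;
rRAKI with c = 0, λ = 1).  These sizes were chosen so the full suite
remains a desk-scale computation while preserving the regime of
interest (contrast mismatch between ACS and scan).

## Known limitations

- Uniform undersampling only; no CAIPIRINHA, partial Fourier, or 3D.
- The sensitivity-map estimate is a Hamming-windowed low-pass of the
  first-echo coil images (default fraction 0.25), not an adaptive
  (eigen-decomposition) combination; its phase is defined up to the
  object phase, so only relative coil phases are testable.
- Circular application assumes Ny divisible by R.
- Training is CPU numpy; it is intended for small scan-specific
  problems, not batch processing of large cohorts.
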