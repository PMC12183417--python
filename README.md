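# cobraki

Scan-specific parallel-imaging reconstruction for 2D Cartesian multi-coil
MRI, with objective hyperparameter selection from the auto-calibration
signals (ACS) alone and a residual-artifact-aware image-quality metric.

## The problem

Accelerated MRI acquires only every R-th phase-encode line of k-space and
recovers the missing lines from the redundancy of a multi-coil receive
array.  *Scan-specific* methods calibrate the interpolation model on a
small fully sampled central block of k-space (the ACS) of the very scan
being reconstructed — no training database.  This package implements and
compares three such models:

- **GRAPPA** — a single complex-valued convolution without bias: a missing
  sample S_c(kx, ky+m) is a complex-weighted sum of neighboring acquired
  samples over all coils, with the kernel solved either in closed form
  (Tikhonov-regularized least squares, `GRAPPA(TR)`) or by gradient
  training (`GRAPPA(TVP)`).
- **rRAKI** — a real-valued 3-layer CNN (real and imaginary parts
  concatenated as channels) in parallel with a linear GRAPPA "short
  connection"; the two outputs are summed.
- **crRAKI** — the complex-valued counterpart: every convolution is an
  exact complex multiply-accumulate (kernel pairs Wr, Wi), and the
  LeakyReLU negative slope `c` acts separately on real and imaginary
  parts, so `c = 1` makes the whole model exactly linear.

Training is supervised on the ACS alone via the **train-validation
partition (TVP)**: the ACS is artificially undersampled into R shifted
line-pair sets; R−1 of them train the offset-m model with the weighted
two-term loss `MSE(pred, target) + λ·MSE(short, target)`, and the last
one drives early stopping and best-epoch selection.  Architectures are
compared by grid search with K-fold cross-validation (K = R) on the
validation k-space MSE, screened with one-tailed Welch t-tests.

Reconstructions are scored with NRMSE, NMAE, PSNR, SSIM and a perceptual
blur score, plus **COBRAI**: the mean, over a brain mask, of the absolute
local Pearson correlation between the residual map (reconstruction −
ground truth, normalized) and the ground truth itself, computed on
sliding 11×11 patches.  Unstructured noise residuals sit near the
analytic null level √(2/(π·121)) ≈ 0.07, while aliasing ghosts and
hallucinated structure drive COBRAI toward 1 even at small RMSE.

A built-in simulator (`cobraki.simkit`) generates multi-coil brain-like
acquisitions — ellipse phantoms with per-tissue relaxation, smooth or
exactly bandlimited coil sensitivities, multi-echo contrast for
integrated/separated ACS modes, and complex Gaussian k-space noise — so
every component is testable without external data.

## Worked example

```python
import cobraki as ck

phantom = ck.make_phantom((64, 64), n_ellipses=5, seed=0)
coils   = ck.make_coil_maps(8, (64, 64), mode="smooth", seed=1)
spec    = ck.AcquisitionSpec(echo_times=(3.2,), noise_sigma=1e-3,
                             matrix=(64, 64), n_coils=8, seed=2)
full = ck.simulate_acquisition(phantom, coils, spec)[0]

und = ck.undersample(full, R=2, m0=1)              # keep every 2nd ky line
acs = ck.make_acs(full, 24, mode="integrated")     # 24 central lines

model = ck.ModelSpec.crraki(8, c=1.0)              # linear crRAKI
cfg   = ck.TrainConfig(lambda_loss=0.0, seed=0)
_, image = ck.reconstruct(und, acs, model, cfg)

gt = ck.combine_sos(ck.kspace_to_image(full.data)).magnitude
report = ck.evaluate_reconstruction(image.magnitude, gt)
print(f"Reff   = {ck.reff_integrated(2, 64, 24):.2f}")
print(f"NRMSE  = {report.nrmse:.4f}")
print(f"PSNR   = {report.psnr:.1f} dB")
print(f"SSIM   = {report.ssim:.4f}")
print(f"COBRAI = {report.cobrai:.3f}")
```

prints

```
Reff   = 1.45
NRMSE  = 0.0051
PSNR   = 46.9 dB
SSIM   = 0.9960
COBRAI = 0.284
```

The effective acceleration 1.45 (not 2) accounts for the 24 ACS lines
acquired on a 64-line matrix; NRMSE/PSNR/SSIM say the magnitude image is
recovered to half a percent, and the COBRAI of 0.28 reports a modest
amount of residual structure correlated with the anatomy (a perfect
reconstruction with purely noisy residuals would sit near 0.07 at this
patch size).

A command-line interface covers the same pipeline:

```bash
cobraki simulate    --out sim.h5 --seed 1 --matrix 64 --coils 8 --acs-lines 24
cobraki gridsearch  --data sim.h5 --family grappa --r 2 --out-csv grid.csv
cobraki reconstruct --data sim.h5 --family crraki --r 2 --out-dir recon/
cobraki evaluate    --data sim.h5 --recon-dir recon/ --out-csv scores.csv
```

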