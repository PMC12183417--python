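"""Image-quality scoring with a focus on structured residual artifacts.

Besides the standard full-reference metrics (NRMSE, NMAE, PSNR, SSIM) and
a no-reference perceptual blur score, this module implements the
COrrelation-Based Residual Artifact map and index:

* the residual map RM is the difference between the reconstructed and
  ground-truth magnitude images, both normalized by the ground-truth
  maximum;
* the COBRA map holds, at every pixel, the absolute Pearson correlation
  between the local RM patch and the co-located ground-truth patch
  (sliding 11x11 windows by default);
* COBRAI is the mean COBRA value over a brain mask.

A perfect reconstruction leaves only unstructured noise in the RM, which
is uncorrelated with the anatomy, so COBRAI is near its small noise floor
(about sqrt(2 / (pi * n)) for n-pixel patches).  Aliasing ghosts and
hallucinated or missing structure correlate with the anatomy and push
COBRAI toward 1 even when their RMSE is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.metrics import structural_similarity
from skimage.morphology import disk

__all__ = [
    "MetricReport",
    "ComparisonResult",
    "nrmse",
    "nmae",
    "psnr",
    "ssim",
    "blur_metric",
    "brain_mask",
    "cobra_map",
    "cobrai",
    "compare_methods",
    "evaluate_reconstruction",
]


@dataclass
class MetricReport:
    nrmse: float
    nmae: float
    psnr: float
    ssim: float
    blur: float
    cobrai: float
    mask: np.ndarray
    patch_size: int = 11


@dataclass
class ComparisonResult:
    shapiro_p: float
    ttest_p: float
    wilcoxon_p: float | None
    normal: bool
    verdict: str  # "a_better" | "not_significant"


def _masked(x: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    return x if mask is None else x[mask]


def nrmse(recon: np.ndarray, gt: np.ndarray, mask: np.ndarray | None = None) -> float:
    """||recon - gt||_2 / ||gt||_2 over masked pixels."""
    r, g = _masked(recon, mask), _masked(gt, mask)
    return float(np.linalg.norm(r - g) / np.linalg.norm(g))


def nmae(recon: np.ndarray, gt: np.ndarray, mask: np.ndarray | None = None) -> float:
    """sum |recon - gt| / sum |gt| over masked pixels."""
    r, g = _masked(recon, mask), _masked(gt, mask)
    return float(np.sum(np.abs(r - g)) / np.sum(np.abs(g)))


def psnr(recon: np.ndarray, gt: np.ndarray, mask: np.ndarray | None = None) -> float:
    """20 log10(max(gt) / rmse) in dB; inf when the images coincide."""
    r, g = _masked(recon, mask), _masked(gt, mask)
    rmse = float(np.sqrt(np.mean((r - g) ** 2)))
    if rmse == 0.0:
        return float("inf")
    return float(20.0 * np.log10(gt.max() / rmse))


def ssim(
    recon: np.ndarray, gt: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Standard SSIM (11x11 Gaussian window, sigma 1.5, K1/K2 = 0.01/0.03).

    Returns (mean over mask, full SSIM map); the data range is taken from
    the ground truth.
    """
    _, smap = structural_similarity(
        gt,
        recon,
        win_size=11,
        gaussian_weights=True,
        sigma=1.5,
        use_sample_covariance=False,
        data_range=float(gt.max()),
        full=True,
    )
    return float(np.mean(_masked(smap, mask))), smap


def blur_metric(image: np.ndarray) -> float:
    """No-reference perceptual blur in [0, 1] (1 = maximally blurred).

    Re-blurs the image with 9-tap horizontal and vertical averaging
    filters and compares the loss of neighboring-pixel variation before
    and after; the final score is the larger of the two directional
    ratios.
    """
    f = np.asarray(image, dtype=float)
    k = np.ones(9) / 9.0
    b_ver = ndimage.correlate1d(f, k, axis=0, mode="nearest")
    b_hor = ndimage.correlate1d(f, k, axis=1, mode="nearest")

    d_f_ver = np.abs(np.diff(f, axis=0))
    d_f_hor = np.abs(np.diff(f, axis=1))
    d_b_ver = np.abs(np.diff(b_ver, axis=0))
    d_b_hor = np.abs(np.diff(b_hor, axis=1))

    v_ver = np.maximum(0.0, d_f_ver - d_b_ver)
    v_hor = np.maximum(0.0, d_f_hor - d_b_hor)

    s_f_ver, s_f_hor = d_f_ver.sum(), d_f_hor.sum()
    if s_f_ver == 0 or s_f_hor == 0:
        return 1.0
    b1 = (s_f_ver - v_ver.sum()) / s_f_ver
    b2 = (s_f_hor - v_hor.sum()) / s_f_hor
    return float(np.clip(max(b1, b2), 0.0, 1.0))


def brain_mask(gt_magnitude: np.ndarray) -> np.ndarray:
    """Otsu threshold + morphological closing + largest connected component."""
    g = np.asarray(gt_magnitude, dtype=float)
    if g.max() <= 0:
        return np.zeros_like(g, dtype=bool)
    th = threshold_otsu(g)
    mask = ndimage.binary_closing(g > th, structure=disk(3))
    labels = cc_label(mask)
    if labels.max() == 0:
        return np.zeros_like(g, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == np.argmax(counts)


def _local_sums(x: np.ndarray, patch: int) -> np.ndarray:
    # sum over the patch window using available pixels only (zero-padded
    # sums; divide by the matching count map for means)
    return ndimage.uniform_filter(x, size=patch, mode="constant", cval=0.0) * (
        patch * patch
    )


def cobra_map(
    recon_mag: np.ndarray, gt_mag: np.ndarray, patch: int = 11
) -> np.ndarray:
    """Absolute local Pearson correlation between the residual map and gt.

    Both magnitudes are normalized by the ground-truth maximum; the
    residual map is their difference.  At every pixel the Pearson r
    between the sliding patch of the residual and the co-located patch of
    the ground truth is computed over the pixels the window actually
    covers (boundary windows use fewer).  Patches with zero variance in
    either operand score 0.
    """
    gt = np.asarray(gt_mag, dtype=float)
    rc = np.asarray(recon_mag, dtype=float)
    if patch > min(gt.shape):
        raise ValueError("patch larger than image")
    peak = gt.max()
    if peak > 0:
        gt = gt / peak
        rc = rc / peak
    rm = rc - gt

    ones = np.ones_like(gt)
    n = _local_sums(ones, patch)
    s_a, s_b = _local_sums(rm, patch), _local_sums(gt, patch)
    s_aa, s_bb = _local_sums(rm * rm, patch), _local_sums(gt * gt, patch)
    s_ab = _local_sums(rm * gt, patch)

    mean_a, mean_b = s_a / n, s_b / n
    var_a = s_aa / n - mean_a**2
    var_b = s_bb / n - mean_b**2
    cov = s_ab / n - mean_a * mean_b

    tol = 1e-12 * max(1.0, float(np.max(s_aa + s_bb)))
    denom = np.sqrt(np.clip(var_a, 0, None) * np.clip(var_b, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((var_a > tol) & (var_b > tol), cov / np.maximum(denom, 1e-300), 0.0)
    return np.clip(np.abs(r), 0.0, 1.0)


def cobrai(
    recon_mag: np.ndarray,
    gt_mag: np.ndarray,
    mask: np.ndarray | None = None,
    patch: int = 11,
) -> float:
    """Mean COBRA value over patch centers inside the mask; in [0, 1]."""
    cmap = cobra_map(recon_mag, gt_mag, patch=patch)
    if mask is None:
        mask = np.ones_like(cmap, dtype=bool)
    if not np.any(mask):
        raise ValueError("empty mask")
    return float(np.mean(cmap[mask]))


def compare_methods(
    scores_a, scores_b, alpha: float = 0.05
) -> ComparisonResult:
    """Paired one-tailed comparison that method a scores lower than b.

    Shapiro-Wilk normality is checked on the paired differences; when it
    holds, a paired one-tailed t-test of mean(a) < mean(b) decides; when
    it fails, the result is flagged and a one-sided Wilcoxon signed-rank
    p-value is reported alongside.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        # degenerate symmetric null: no evidence either way
        return ComparisonResult(1.0, 0.5, None, True, "not_significant")
    shapiro_p = float(stats.shapiro(diffs).pvalue) if np.ptp(diffs) > 0 else 1.0
    ttest_p = float(stats.ttest_rel(a, b, alternative="less").pvalue)
    normal = shapiro_p >= alpha
    wilcoxon_p = None
    if not normal:
        wilcoxon_p = float(
            stats.wilcoxon(a, b, alternative="less", zero_method="wilcox").pvalue
        )
    decisive_p = ttest_p if normal else wilcoxon_p
    verdict = "a_better" if decisive_p < alpha else "not_significant"
    return ComparisonResult(
        shapiro_p=shapiro_p,
        ttest_p=ttest_p,
        wilcoxon_p=wilcoxon_p,
        normal=normal,
        verdict=verdict,
    )


def evaluate_reconstruction(
    recon_mag: np.ndarray,
    gt_mag: np.ndarray,
    mask: np.ndarray | None = None,
    patch: int = 11,
) -> MetricReport:
    """All per-slice scores in one report; the mask defaults to the
    Otsu-based brain mask of the ground truth."""
    if mask is None:
        mask = brain_mask(gt_mag)
    if not np.any(mask):
        raise ValueError("empty evaluation mask")
    s, _ = ssim(recon_mag, gt_mag, mask)
    return MetricReport(
        nrmse=nrmse(recon_mag, gt_mag, mask),
        nmae=nmae(recon_mag, gt_mag, mask),
        psnr=psnr(recon_mag, gt_mag, mask),
        ssim=s,
        blur=blur_metric(recon_mag),
        cobrai=cobrai(recon_mag, gt_mag, mask, patch=patch),
        mask=mask,
        patch_size=patch,
    )
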