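"""Core k-space data model and utilities.

Multi-coil Cartesian 2D k-space is held as a complex tensor with axes
``(coil, kx, ky)``; the readout direction kx is always fully sampled and
acceleration acts along the phase-encode direction ky.  All Fourier
transforms use the centered, orthonormal convention (DC at the matrix
center, unitary scaling), so Parseval's identity holds exactly.

The documented line-index math (``line_index_set``) follows the
conventional 1-based notation TR(m) = {m, m+R, m+2R, ...}; everywhere else
indices are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "MultiCoilKSpace",
    "ACSBlock",
    "CombinedImage",
    "line_index_set",
    "undersample",
    "merge_predictions",
    "kspace_to_image",
    "image_to_kspace",
    "combine_sos",
    "estimate_sensitivity_lowpass",
    "combine_sensitivity",
    "reff_integrated",
    "reff_separated",
]

_EPS_REL = 1e-8


@dataclass
class MultiCoilKSpace:
    """Multi-coil 2D k-space with its sampling metadata.

    Parameters
    ----------
    data : complex ndarray, shape (n_coils, Nx, Ny)
    sampled_ky : int ndarray
        0-based ky indices that were actually acquired.
    R : int
        Nominal acceleration rate along ky (1 = fully sampled).
    m0 : int
        1-based phase of the uniform pattern; for a uniform pattern the
        acquired lines are ``m0-1, m0-1+R, ...`` in 0-based indexing.
    """

    data: np.ndarray
    sampled_ky: np.ndarray = field(default=None)  # type: ignore[assignment]
    R: int = 1
    m0: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("k-space data must be (coil, kx, ky)")
        if self.sampled_ky is None:
            self.sampled_ky = np.arange(self.data.shape[2])
        self.sampled_ky = np.asarray(self.sampled_ky, dtype=int)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class ACSBlock:
    """Fully sampled central k-space block used for calibration.

    ``mode`` records whether the ACS lines were carved from the accelerated
    scan itself (``integrated``: same contrast, lines reusable for data
    consistency) or from a separate fast pre-scan (``separated``: different
    contrast).  ``ky_origin`` is the 0-based position of the first ACS line
    inside the full ky grid.
    """

    data: np.ndarray
    mode: str = "integrated"
    ky_origin: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ACS data must be (coil, kx, ky)")
        if self.mode not in ("integrated", "separated"):
            raise ValueError(f"unknown ACS mode {self.mode!r}")

    @property
    def n_lines(self) -> int:
        return self.data.shape[2]


@dataclass
class CombinedImage:
    magnitude: np.ndarray
    phase: np.ndarray | None
    combination: str  # "sos" | "sensitivity"


# ---------------------------------------------------------------------------
# line index bookkeeping


def line_index_set(R: int, m: int, Ny: int) -> np.ndarray:
    """1-based phase-encode index set TR(m) = {m, m+R, m+2R, ...} within [1, Ny]."""
    if R < 1 or m < 1:
        raise ValueError("require R >= 1 and m >= 1")
    return np.arange(m, Ny + 1, R)


def undersample(full: MultiCoilKSpace, R: int, m0: int = 1) -> MultiCoilKSpace:
    """Retain only the uniform every-R ky lines of phase m0; zero the rest."""
    if not 1 <= m0 <= R:
        raise ValueError("require 1 <= m0 <= R")
    Ny = full.data.shape[2]
    kept = np.arange(m0 - 1, Ny, R)
    out = np.zeros_like(full.data)
    out[:, :, kept] = full.data[:, :, kept]
    return MultiCoilKSpace(out, sampled_ky=kept, R=R, m0=m0)


def merge_predictions(
    acquired: MultiCoilKSpace,
    predictions: Mapping[int, np.ndarray],
    acs: ACSBlock | None = None,
) -> MultiCoilKSpace:
    """Assemble a full-grid k-space estimate from acquired lines + predictions.

    ``predictions`` maps the view index m in {2..R} (view m occupies the ky
    lines shifted by m-1 from the acquired pattern) to a full-grid tensor;
    only the lines belonging to that view are read from it.  Acquired lines
    are copied verbatim, and — when an integrated-mode ACS is supplied — the
    measured ACS lines overwrite predictions at their positions (data
    consistency).
    """
    R, m0 = acquired.R, acquired.m0
    Nc, Nx, Ny = acquired.data.shape
    out = np.zeros_like(acquired.data)
    for m in range(2, R + 1):
        if m not in predictions:
            raise KeyError(f"missing prediction for view m={m}")
        pred = np.asarray(predictions[m])
        if pred.shape != acquired.data.shape:
            raise ValueError("prediction shape mismatch")
        pos = np.arange((m0 - 1 + m - 1) % R, Ny, R)
        out[:, :, pos] = pred[:, :, pos]
    out[:, :, acquired.sampled_ky] = acquired.data[:, :, acquired.sampled_ky]
    if acs is not None and acs.mode == "integrated":
        j0 = acs.ky_origin
        out[:, :, j0 : j0 + acs.n_lines] = acs.data
    return MultiCoilKSpace(out, sampled_ky=np.arange(Ny), R=1, m0=1)


# ---------------------------------------------------------------------------
# Fourier transforms and coil combination


def kspace_to_image(k: np.ndarray) -> np.ndarray:
    """Centered orthonormal inverse 2-D DFT over the trailing two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(k, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def image_to_kspace(img: np.ndarray) -> np.ndarray:
    """Centered orthonormal forward 2-D DFT over the trailing two axes."""
    axes = (-2, -1)
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def combine_sos(coil_images: np.ndarray) -> CombinedImage:
    """Root-sum-of-squares magnitude combination (phase is discarded)."""
    mag = np.sqrt(np.sum(np.abs(coil_images) ** 2, axis=0))
    return CombinedImage(magnitude=mag, phase=None, combination="sos")


def estimate_sensitivity_lowpass(
    first_echo_coil_images: np.ndarray,
    filter_fraction: float = 0.25,
    taper: str = "hamming",
) -> np.ndarray:
    """Estimate complex coil sensitivities by low-pass filtering coil images.

    Each coil image is filtered with a central k-space window of fractional
    width ``filter_fraction`` per dimension (Hamming-tapered by default),
    then normalized by the root-sum-of-squares over coils with a small
    relative floor so background pixels stay finite.
    """
    if not 0 < filter_fraction <= 1:
        raise ValueError("filter_fraction must lie in (0, 1]")
    imgs = np.asarray(first_echo_coil_images)
    Nc, Nx, Ny = imgs.shape
    k = image_to_kspace(imgs)

    def window(n: int) -> np.ndarray:
        w = np.zeros(n)
        width = max(1, int(round(filter_fraction * n)))
        start = (n - width) // 2
        if taper == "hamming":
            w[start : start + width] = np.hamming(width)
        elif taper == "none":
            w[start : start + width] = 1.0
        else:
            raise ValueError(f"unknown taper {taper!r}")
        return w

    k = k * np.outer(window(Nx), window(Ny))[None]
    smooth = kspace_to_image(k)
    rss = np.sqrt(np.sum(np.abs(smooth) ** 2, axis=0))
    floor = _EPS_REL * max(rss.max(), np.finfo(float).tiny)
    return smooth / np.maximum(rss, floor)[None]


def combine_sensitivity(
    coil_images: np.ndarray, sensitivities: np.ndarray
) -> CombinedImage:
    """Phase-preserving sensitivity-weighted coil combination.

    combined = sum_c conj(s_c) I_c / max(sum_c |s_c|^2, eps).
    """
    num = np.sum(np.conj(sensitivities) * coil_images, axis=0)
    den = np.sum(np.abs(sensitivities) ** 2, axis=0)
    floor = _EPS_REL * max(den.max(), np.finfo(float).tiny)
    combined = num / np.maximum(den, floor)
    return CombinedImage(
        magnitude=np.abs(combined), phase=np.angle(combined), combination="sensitivity"
    )


# ---------------------------------------------------------------------------
# effective acceleration rates


def reff_integrated(Ry: int, Ny: int, Nyacs: int) -> float:
    """Effective acceleration when the ACS lines are part of the scan.

    Reff = Ry * Ny / (Ny + (Ry - 1) * Nyacs).
    """
    if Nyacs > Ny:
        raise ValueError("Nyacs cannot exceed Ny")
    return Ry * Ny / (Ny + (Ry - 1) * Nyacs)


def reff_separated(T_acs: float, T_full: float, Ry: int) -> float:
    """Effective acceleration when the ACS comes from a separate pre-scan.

    Reff = (T_acs + T_full) / (T_acs + T_full / Ry), with times in seconds.
    """
    if T_full <= 0:
        raise ValueError("T_full must be positive")
    if T_acs < 0:
        raise ValueError("T_acs must be non-negative")
    return (T_acs + T_full) / (T_acs + T_full / Ry)
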