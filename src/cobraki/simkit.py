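"""Synthetic multi-coil brain-like acquisitions.

Generates everything the reconstruction and selection modules need without
any external data: piecewise-constant ellipse phantoms with per-tissue
relaxation rates and smooth field/phase maps, complex coil sensitivities
(smooth Gaussian lobes or exactly bandlimited spectra), a multi-echo
gradient-echo forward model with complex Gaussian k-space noise, and ACS
extraction in integrated or separated mode.

Two properties matter for testing downstream code:

* every generator is a pure function of its seed;
* in ``bandlimited`` coil mode with noiseless data, the coil spectra are
  confined to a small box, so an exact linear (GRAPPA-style) k-space
  interpolation kernel exists — the closed-form oracle regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kspace import ACSBlock, MultiCoilKSpace, image_to_kspace, kspace_to_image

__all__ = [
    "PhantomImage",
    "CoilMaps",
    "AcquisitionSpec",
    "make_phantom",
    "make_coil_maps",
    "simulate_acquisition",
    "make_acs",
]


@dataclass
class PhantomImage:
    """Piecewise-constant object with relaxation and field maps.

    ``magnitude`` is in arbitrary units and zero outside the object,
    ``phase`` in radians (zero outside support), ``relaxation_rate`` is an
    effective R2* in 1/ms, and ``field_offset`` an off-resonance phase
    accrual rate in rad/ms.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    tissue_labels: np.ndarray
    relaxation_rate: np.ndarray
    field_offset: np.ndarray

    @property
    def support(self) -> np.ndarray:
        return self.magnitude > 0


@dataclass
class CoilMaps:
    sensitivities: np.ndarray  # complex, (coil, x, y)
    mode: str  # "smooth" | "bandlimited"
    kspace_support: tuple[int, int] | None = None

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]


@dataclass
class AcquisitionSpec:
    """Multi-echo 2D GRE-like protocol parameters."""

    echo_times: tuple[float, ...] = (3.2,)  # ms
    noise_sigma: float = 0.0  # per real/imag component, k-space units
    matrix: tuple[int, int] = (64, 64)
    n_coils: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        te = tuple(float(t) for t in self.echo_times)
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo_times must be strictly increasing")
        if min(self.matrix) < 16:
            raise ValueError("matrix dimensions must be >= 16")
        if self.n_coils < 2:
            raise ValueError("need at least 2 coils")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.echo_times = te


def _grid(matrix: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = matrix
    x = np.linspace(-1.0, 1.0, nx, endpoint=False) + 1.0 / nx
    y = np.linspace(-1.0, 1.0, ny, endpoint=False) + 1.0 / ny
    return np.meshgrid(x, y, indexing="ij")


def _ellipse_mask(xx, yy, center, axes, angle) -> np.ndarray:
    dx, dy = xx - center[0], yy - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _poly2(xx, yy, coeffs) -> np.ndarray:
    c0, cx, cy, cxx, cyy, cxy = coeffs
    return c0 + cx * xx + cy * yy + cxx * xx**2 + cyy * yy**2 + cxy * xx * yy


def make_phantom(
    matrix: tuple[int, int] = (64, 64), n_ellipses: int = 4, seed: int = 0
) -> PhantomImage:
    """Overlapping-ellipse phantom with per-tissue relaxation rates.

    The first ellipse is a large centered "head" outline; subsequent
    ellipses are random internal structures that overwrite the tissue label
    where they land.  Field offset and phase are low-order polynomials.
    """
    if min(matrix) < 16:
        raise ValueError("matrix dimensions must be >= 16")
    if n_ellipses < 1:
        raise ValueError("need at least one ellipse")
    rng = np.random.default_rng(seed)
    xx, yy = _grid(matrix)

    labels = np.zeros(matrix, dtype=int)
    labels[_ellipse_mask(xx, yy, (0.0, 0.0), (0.75, 0.85), 0.0)] = 1
    support = labels > 0
    for k in range(2, n_ellipses + 1):
        center = rng.uniform(-0.35, 0.35, size=2)
        axes = rng.uniform(0.08, 0.30, size=2)
        angle = rng.uniform(0.0, np.pi)
        inner = _ellipse_mask(xx, yy, center, axes, angle) & support
        labels[inner] = k

    n_labels = n_ellipses + 1
    mag_by_label = np.concatenate([[0.0, 0.8], rng.uniform(0.3, 1.0, n_labels - 2)])
    r2_by_label = np.concatenate([[0.0], rng.uniform(0.005, 0.05, n_labels - 1)])
    magnitude = mag_by_label[labels]
    relaxation = r2_by_label[labels]

    field_offset = _poly2(xx, yy, rng.uniform(-0.05, 0.05, 6))
    phase = np.where(support, _poly2(xx, yy, rng.uniform(-0.5, 0.5, 6)), 0.0)
    return PhantomImage(
        magnitude=magnitude,
        phase=phase,
        tissue_labels=labels,
        relaxation_rate=relaxation,
        field_offset=field_offset,
    )


def make_texture_phantom(
    matrix: tuple[int, int] = (64, 64), seed: int = 0
) -> PhantomImage:
    """Full-support random-texture object with an approximately flat
    k-space spectrum.

    Used for the exact-interpolation oracle regime: together with
    bandlimited coils, the flat spectrum keeps the GRAPPA calibration
    problem well conditioned on its row space, so iterative training can
    actually attain the exact solution instead of stalling in poorly
    excited directions.  Relaxation and field maps are zero.
    """
    if min(matrix) < 16:
        raise ValueError("matrix dimensions must be >= 16")
    rng = np.random.default_rng(seed)
    zeros = np.zeros(matrix)
    return PhantomImage(
        magnitude=rng.uniform(0.5, 1.5, matrix),
        phase=rng.uniform(-np.pi, np.pi, matrix),
        tissue_labels=np.ones(matrix, dtype=int),
        relaxation_rate=zeros.copy(),
        field_offset=zeros.copy(),
    )


def make_coil_maps(
    n_coils: int,
    matrix: tuple[int, int],
    mode: str = "smooth",
    kspace_support: tuple[int, int] | None = None,
    seed: int = 0,
) -> CoilMaps:
    """Complex coil sensitivities.

    smooth
        Gaussian-lobe magnitudes centered at equally spaced angles around
        the field of view, each with a smooth (linear) phase ramp.
    bandlimited
        Maps synthesized from random spectra confined to a central
        ``kspace_support`` box (exactly zero outside it), with a boosted DC
        tap so the root-sum-of-squares never vanishes.  This is the regime
        where GRAPPA interpolation is exact.
    """
    if n_coils < 2:
        raise ValueError("need at least 2 coils")
    rng = np.random.default_rng(seed)
    nx, ny = matrix
    if mode == "smooth":
        xx, yy = _grid(matrix)
        sens = np.empty((n_coils,) + tuple(matrix), dtype=complex)
        for c in range(n_coils):
            theta = 2 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
            cx, cy = 1.15 * np.cos(theta), 1.15 * np.sin(theta)
            lobe = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2)) / (2 * 0.8**2))
            ramp = rng.uniform(-0.8, 0.8, 3)
            sens[c] = lobe * np.exp(1j * (ramp[0] * xx + ramp[1] * yy + ramp[2]))
        return CoilMaps(sens, mode="smooth")
    if mode == "bandlimited":
        if kspace_support is None:
            raise ValueError("bandlimited mode requires kspace_support")
        sx, sy = kspace_support
        if sx > nx or sy > ny:
            raise ValueError("kspace_support cannot exceed the matrix")
        spec = np.zeros((n_coils, nx, ny), dtype=complex)
        x0, y0 = (nx - sx) // 2, (ny - sy) // 2
        box = rng.normal(size=(n_coils, sx, sy)) + 1j * rng.normal(
            size=(n_coils, sx, sy)
        )
        spec[:, x0 : x0 + sx, y0 : y0 + sy] = box
        # boost a near-DC tap (inside the box) so the root-sum-of-squares
        # magnitude stays positive everywhere
        dc_x = min(max(nx // 2, x0), x0 + sx - 1)
        dc_y = min(max(ny // 2, y0), y0 + sy - 1)
        spec[:, dc_x, dc_y] += 4.0 * np.max(np.abs(box))
        sens = kspace_to_image(spec)
        return CoilMaps(sens, mode="bandlimited", kspace_support=(sx, sy))
    raise ValueError(f"unknown coil-map mode {mode!r}")


def coil_images(
    phantom: PhantomImage, coils: CoilMaps, echo_time: float
) -> np.ndarray:
    """Noiseless complex coil images at one echo time (ms)."""
    decay = phantom.magnitude * np.exp(-echo_time * phantom.relaxation_rate)
    ph = np.exp(1j * (phantom.phase + echo_time * phantom.field_offset))
    return coils.sensitivities * (decay * ph)[None]


def simulate_acquisition(
    phantom: PhantomImage, coils: CoilMaps, spec: AcquisitionSpec
) -> list[MultiCoilKSpace]:
    """Forward-model a multi-echo acquisition; one full k-space per echo.

    Per echo TE the coil image is sensitivity x magnitude x exp(-TE*R2*)
    x exp(i(phase + TE*field_offset)); k-space is its centered orthonormal
    DFT per coil plus iid circularly symmetric complex Gaussian noise of
    std ``noise_sigma`` per real/imag component.
    """
    if phantom.magnitude.shape != tuple(spec.matrix) or coils.sensitivities.shape[
        1:
    ] != tuple(spec.matrix):
        raise ValueError("phantom, coil and spec shapes disagree")
    if coils.n_coils != spec.n_coils:
        raise ValueError("coil count mismatch")
    rng = np.random.default_rng(spec.seed)
    out = []
    for te in spec.echo_times:
        k = image_to_kspace(coil_images(phantom, coils, te))
        if spec.noise_sigma > 0:
            k = k + spec.noise_sigma * (
                rng.normal(size=k.shape) + 1j * rng.normal(size=k.shape)
            )
        out.append(MultiCoilKSpace(k, R=1, m0=1))
    return out


def make_acs(
    full: MultiCoilKSpace,
    n_acs_lines: int,
    mode: str = "integrated",
    separated_source: MultiCoilKSpace | None = None,
) -> ACSBlock:
    """Cut the central ky lines out of a fully sampled k-space.

    Integrated mode reads the lines from ``full`` itself; separated mode
    reads them from ``separated_source``, a different-contrast acquisition
    of the same object and coils.  For even gaps the window starts at
    floor((Ny - n)/2) (ties toward the lower index).
    """
    Ny = full.data.shape[2]
    if n_acs_lines > Ny:
        raise ValueError("n_acs_lines cannot exceed Ny")
    if mode == "separated":
        if separated_source is None:
            raise ValueError("separated mode requires separated_source")
        src = separated_source
    elif mode == "integrated":
        src = full
    else:
        raise ValueError(f"unknown ACS mode {mode!r}")
    start = (Ny - n_acs_lines) // 2
    return ACSBlock(
        data=src.data[:, :, start : start + n_acs_lines].copy(),
        mode=mode,
        ky_origin=start,
    )
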