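"""Interpolation model families: GRAPPA, rRAKI and crRAKI.

All three models predict, for one line offset m in {1..R-1}, the missing
ky lines of a uniformly undersampled multi-coil k-space from the stack of
acquired lines.  Convolutions act on the *decimated* acquired-line grid:
a ky kernel tap steps over consecutive acquired lines (spacing R in
full-grid units) while kx runs at full resolution.

GRAPPA   single complex-valued convolution, no bias.
rRAKI    real-valued 3-layer CNN (real/imag parts concatenated as
         channels) plus a linear GRAPPA "short connection"; the two path
         outputs are summed.
crRAKI   the complex-valued counterpart: every convolution is an exact
         complex multiply-accumulate implemented with a kernel pair
         (Wr, Wi), and the LeakyReLU acts separately on real and
         imaginary parts (the split form is the identity at c=1, so the
         c=1 limit is exactly linear).

No layer anywhere carries a bias term.  Activations follow the three-layer
RAKI convention: after layers 1 and 2 only.

Convolutions are "valid" (no padding) during calibration — the training
targets are cropped to the common output support — and circular (periodic
in k-space, which the DFT convention makes exact) when a trained model is
applied to reconstruct full lines.

The module also contains the gradient engine used by the training loop:
im2col convolutions with hand-derived adjoints.  For complex kernels the
real and imaginary parts are independent real parameters, and the
returned gradient array packs dL/dWr + i dL/dWi.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .kspace import ACSBlock, MultiCoilKSpace

__all__ = [
    "ModelSpec",
    "ModelWeights",
    "leaky_relu",
    "complex_conv",
    "grappa_forward",
    "rraki_forward",
    "crraki_forward",
    "predict_offset",
    "fit_grappa_tikhonov",
    "parameter_count",
]

FAMILIES = ("grappa", "rraki", "crraki")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for one interpolation model.

    ``kernel_sizes``/``depths`` describe the CNN path (empty for GRAPPA);
    depths are stored in the family's native units, i.e. real channel
    counts for rRAKI (input 2*Nc) and complex map counts for crRAKI
    (input Nc).  ``residual_kernel`` is the GRAPPA kernel for the grappa
    family and the short-connection kernel otherwise.  ``c`` is the
    LeakyReLU negative slope: 0 = pure ReLU, 1 = identity (linear model).
    """

    family: str
    n_coils: int
    kernel_sizes: tuple[tuple[int, int], ...] = ()
    depths: tuple[tuple[int, int], ...] = ()
    residual_kernel: tuple[int, int] = (5, 4)
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("linearity parameter c must lie in [0, 1]")
        if len(self.kernel_sizes) != len(self.depths):
            raise ValueError("kernel_sizes and depths must have equal length")
        io = self.n_coils * (2 if self.family == "rraki" else 1)
        if self.depths:
            if self.depths[0][0] != io or self.depths[-1][1] != io:
                raise ValueError("CNN depths must start/end at the coil count")
            for (_, d_out), (d_in, _) in zip(self.depths, self.depths[1:]):
                if d_out != d_in:
                    raise ValueError("layer depth chain broken")
        elif self.family != "grappa":
            raise ValueError("rRAKI/crRAKI require CNN layers")

    # -- canonical architectures --------------------------------------
    @classmethod
    def grappa(
        cls, n_coils: int, kernel: tuple[int, int] = (5, 4)
    ) -> "ModelSpec":
        return cls(family="grappa", n_coils=n_coils, residual_kernel=kernel, c=1.0)

    @classmethod
    def rraki(
        cls,
        n_coils: int,
        first: tuple[int, int] = (5, 2),
        d1: int = 16,
        d2: int = 4,
        third: tuple[int, int] = (3, 2),
        residual: tuple[int, int] = (5, 2),
        c: float = 0.0,
    ) -> "ModelSpec":
        """Real-valued residual RAKI; d1/d2 in complex units (real = 2x)."""
        n = 2 * n_coils
        return cls(
            family="rraki",
            n_coils=n_coils,
            kernel_sizes=(first, (1, 1), third),
            depths=((n, 2 * d1), (2 * d1, 2 * d2), (2 * d2, n)),
            residual_kernel=residual,
            c=c,
        )

    @classmethod
    def crraki(
        cls,
        n_coils: int,
        first: tuple[int, int] = (5, 2),
        d1: int = 16,
        d2: int = 32,
        third: tuple[int, int] = (3, 2),
        residual: tuple[int, int] = (1, 1),
        c: float = 1.0,
    ) -> "ModelSpec":
        """Complex-valued residual RAKI with the published default depths."""
        n = n_coils
        return cls(
            family="crraki",
            n_coils=n_coils,
            kernel_sizes=(first, (1, 1), third),
            depths=((n, d1), (d1, d2), (d2, n)),
            residual_kernel=residual,
            c=c,
        )

    @property
    def is_complex(self) -> bool:
        return self.family in ("grappa", "crraki")

    def with_linearity(self, c: float) -> "ModelSpec":
        return replace(self, c=c)

    def label(self) -> str:
        if self.family == "grappa":
            return f"grappa{list(self.residual_kernel)}"
        ks = "x".join(f"{k[0]},{k[1]}" for k in self.kernel_sizes)
        ds = "-".join(str(d[1]) for d in self.depths[:-1])
        return f"{self.family}[{ks}]d{ds}r{list(self.residual_kernel)}c{self.c:g}"


@dataclass
class ModelWeights:
    """Per-layer kernels; complex families hold complex arrays Wr + i Wi.

    Layer arrays are shaped (d_out, d_in, nx, ny); ``residual`` holds the
    GRAPPA / short-connection kernel (for grappa it is the only kernel).
    There are no bias terms.
    """

    layers: list[np.ndarray]
    residual: np.ndarray

    def copy(self) -> "ModelWeights":
        return ModelWeights([w.copy() for w in self.layers], self.residual.copy())


# ---------------------------------------------------------------------------
# primitive ops


def leaky_relu(x: np.ndarray, c: float) -> np.ndarray:
    """LeakyReLU with negative slope c; split over real/imag for complex."""
    x = np.asarray(x)
    if np.iscomplexobj(x):
        return leaky_relu(x.real, c) + 1j * leaky_relu(x.imag, c)
    return np.where(x >= 0, x, c * x)


def _leaky_relu_grad(x: np.ndarray, g: np.ndarray, c: float) -> np.ndarray:
    if np.iscomplexobj(x):
        return _leaky_relu_grad(x.real, g.real, c) + 1j * _leaky_relu_grad(
            x.imag, g.imag, c
        )
    return np.where(x >= 0, g, c * g)


def _sliding(x: np.ndarray, kx: int, ky: int) -> np.ndarray:
    if x.shape[1] < kx or x.shape[2] < ky:
        raise ValueError(
            f"kernel ({kx},{ky}) larger than input extent {x.shape[1:]}"
        )
    return np.lib.stride_tricks.sliding_window_view(x, (kx, ky), axis=(1, 2))


def conv_valid(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Plain multiply-accumulate valid convolution (cross-correlation form).

    x: (c_in, H, W); W: (c_out, c_in, kx, ky) -> (c_out, H-kx+1, W-ky+1).
    Works identically for real and complex operands (no conjugation), so a
    complex kernel performs the exact complex multiply-accumulate.
    """
    sw = _sliding(x, W.shape[2], W.shape[3])
    return np.einsum("cijab,ocab->oij", sw, W, optimize=True)


def conv_circular(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Periodic convolution, output anchored at the ((k-1)//2) tap."""
    kx, ky = W.shape[2], W.shape[3]
    ox, oy = (kx - 1) // 2, (ky - 1) // 2
    xp = np.pad(x, ((0, 0), (ox, kx - 1 - ox), (oy, ky - 1 - oy)), mode="wrap")
    return conv_valid(xp, W)


def _conv_valid_backward(
    x: np.ndarray, W: np.ndarray, G: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoints of conv_valid for a real-valued loss.

    G packs dL/dRe(out) + i dL/dIm(out).  Returns (dW, dX) in the same
    packing; for complex kernels dW = dL/dWr + i dL/dWi.
    """
    kx, ky = W.shape[2], W.shape[3]
    sw = _sliding(x, kx, ky)
    dW = np.einsum("cijab,oij->ocab", np.conj(sw), G, optimize=True)
    Gp = np.pad(G, ((0, 0), (kx - 1, kx - 1), (ky - 1, ky - 1)))
    Wt = np.conj(W[:, :, ::-1, ::-1]).transpose(1, 0, 2, 3)
    dX = conv_valid(Gp, Wt)
    return dW, dX


def complex_conv(
    inp: np.ndarray, Wr: np.ndarray, Wi: np.ndarray, mode: str = "valid"
) -> np.ndarray:
    """Complex convolution via a real kernel pair: (Wr + i Wi) * (X + i Y)."""
    W = np.asarray(Wr) + 1j * np.asarray(Wi)
    if mode == "valid":
        return conv_valid(np.asarray(inp, dtype=complex), W)
    if mode == "circular":
        return conv_circular(np.asarray(inp, dtype=complex), W)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# path geometry

# In valid mode, output element (i, j) of a chain of convolutions
# corresponds to the input anchor coordinate (i + off_x, j + off_y) with
# off = sum over layers of (k - 1) // 2: for an even ky extent the target
# line sits just after the lower-middle tap, i.e. between the two central
# taps once the +m offset is applied.  The same per-layer anchoring is used
# by conv_circular, so calibration and application agree by construction.


def _path_offset(kernels: Sequence[tuple[int, int]]) -> tuple[int, int]:
    return (
        sum((k[0] - 1) // 2 for k in kernels),
        sum((k[1] - 1) // 2 for k in kernels),
    )


def _common_box(
    shapes_offsets: Sequence[tuple[tuple[int, int], tuple[int, int]]]
) -> tuple[int, int, int, int]:
    """Intersection of path outputs in input-anchor coordinates."""
    a0 = max(off[0] for _, off in shapes_offsets)
    b0 = max(off[1] for _, off in shapes_offsets)
    a1 = min(off[0] + sh[0] for sh, off in shapes_offsets)
    b1 = min(off[1] + sh[1] for sh, off in shapes_offsets)
    if a1 <= a0 or b1 <= b0:
        raise ValueError("paths have no common valid output support")
    return a0, a1, b0, b1


def _crop(out: np.ndarray, off: tuple[int, int], box) -> np.ndarray:
    a0, a1, b0, b1 = box
    return out[:, a0 - off[0] : a1 - off[0], b0 - off[1] : b1 - off[1]]


# ---------------------------------------------------------------------------
# forward evaluation on acquired-line stacks


def _to_real_channels(stack: np.ndarray) -> np.ndarray:
    return np.concatenate([stack.real, stack.imag], axis=0)


def _to_complex(chan: np.ndarray) -> np.ndarray:
    n = chan.shape[0] // 2
    return chan[:n] + 1j * chan[n:]


def _stack_forward(
    stack: np.ndarray, weights: ModelWeights, spec: ModelSpec, mode: str
):
    """Evaluate one model on a (Nc, Nx, n_lines) acquired-line stack.

    Returns (prediction, short_prediction, box) where box is the common
    support in input-anchor coordinates ((a0, a1, b0, b1); the full extent
    in circular mode).
    """
    conv = conv_valid if mode == "valid" else conv_circular
    if spec.family == "grappa":
        out = conv(stack, weights.residual)
        off = _path_offset([weights.residual.shape[2:]])
        if mode == "valid":
            box = (off[0], off[0] + out.shape[1], off[1], off[1] + out.shape[2])
        else:
            box = (0, stack.shape[1], 0, stack.shape[2])
        return out, out, box

    x0 = _to_real_channels(stack) if spec.family == "rraki" else stack.astype(complex)
    h = x0
    for li, W in enumerate(weights.layers):
        h = conv(h, W)
        if li < len(weights.layers) - 1:
            h = leaky_relu(h, spec.c)
    short = conv(x0, weights.residual)
    if mode == "valid":
        off_cnn = _path_offset(spec.kernel_sizes)
        off_res = _path_offset([spec.residual_kernel])
        box = _common_box([(h.shape[1:], off_cnn), (short.shape[1:], off_res)])
        h = _crop(h, off_cnn, box)
        short = _crop(short, off_res, box)
    else:
        box = (0, stack.shape[1], 0, stack.shape[2])
    if spec.family == "rraki":
        h, short = _to_complex(h), _to_complex(short)
    return h + short, short, box


def _acquired_stack(Su: MultiCoilKSpace) -> tuple[np.ndarray, np.ndarray]:
    pos = np.sort(np.asarray(Su.sampled_ky))
    return Su.data[:, :, pos], pos


def grappa_forward(
    Su: MultiCoilKSpace, weights: ModelWeights, spec: ModelSpec, m: int = 1
) -> np.ndarray:
    """Predict the offset-m missing lines of a uniformly undersampled scan.

    Returns a full-grid (Nc, Nx, Ny) tensor, nonzero only on the predicted
    lines (acquired position + m, periodic in ky).
    """
    if spec.family != "grappa":
        raise ValueError("spec.family must be 'grappa'")
    return predict_offset(Su, weights, spec, m)


def rraki_forward(
    Su: MultiCoilKSpace, weights: ModelWeights, spec: ModelSpec, m: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Full-grid (prediction, short-connection prediction) for offset m."""
    if spec.family != "rraki":
        raise ValueError("spec.family must be 'rraki'")
    return _predict_offset_both(Su, weights, spec, m)


def crraki_forward(
    Su: MultiCoilKSpace, weights: ModelWeights, spec: ModelSpec, m: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    if spec.family != "crraki":
        raise ValueError("spec.family must be 'crraki'")
    return _predict_offset_both(Su, weights, spec, m)


def _scatter(pred: np.ndarray, pos: np.ndarray, m: int, Ny: int) -> np.ndarray:
    out = np.zeros((pred.shape[0], pred.shape[1], Ny), dtype=complex)
    out[:, :, (pos + m) % Ny] = pred
    return out


def _predict_offset_both(Su, weights, spec, m):
    stack, pos = _acquired_stack(Su)
    Ny = Su.data.shape[2]
    if Ny % Su.R != 0:
        raise ValueError("circular application requires Ny divisible by R")
    pred, short, _ = _stack_forward(stack, weights, spec, mode="circular")
    return _scatter(pred, pos, m, Ny), _scatter(short, pos, m, Ny)


def predict_offset(
    Su: MultiCoilKSpace, weights: ModelWeights, spec: ModelSpec, m: int
) -> np.ndarray:
    """Full-grid prediction of the lines at offset m for any family."""
    if spec.family == "grappa":
        stack, pos = _acquired_stack(Su)
        Ny = Su.data.shape[2]
        if Ny % Su.R != 0:
            raise ValueError("circular application requires Ny divisible by R")
        pred, _, _ = _stack_forward(stack, weights, spec, mode="circular")
        return _scatter(pred, pos, m, Ny)
    return _predict_offset_both(Su, weights, spec, m)[0]


# ---------------------------------------------------------------------------
# loss + gradients (used by the training module)


def forward_backward(
    stack: np.ndarray,
    target: np.ndarray,
    weights: ModelWeights,
    spec: ModelSpec,
    lam: float,
):
    """Loss and parameter gradients on one calibration batch.

    ``stack`` is the (Nc, Nx, n_in_lines) input-line stack, ``target`` the
    matching (Nc, Nx, n_target_lines) array indexed by anchor coordinates
    and already restricted to lines that exist; the prediction is cropped
    to the intersection of the valid support and the available targets.

    Returns (loss, grads, pred, tgt_crop) where grads mirrors the layout
    produced by :func:`pack_params` (complex arrays pack dL/dWr + i dL/dWi).
    """
    conv = conv_valid
    is_grappa = spec.family == "grappa"
    is_real = spec.family == "rraki"
    x0 = _to_real_channels(stack) if is_real else stack.astype(complex)

    acts = [x0]
    pre = []
    if not is_grappa:
        h = x0
        for li, W in enumerate(weights.layers):
            z = conv(h, W)
            pre.append(z)
            h = leaky_relu(z, spec.c) if li < len(weights.layers) - 1 else z
            acts.append(h)
        off_cnn = _path_offset(spec.kernel_sizes)
    short_full = conv(x0, weights.residual)
    off_res = _path_offset([spec.residual_kernel])

    if is_grappa:
        box = (
            off_res[0],
            off_res[0] + short_full.shape[1],
            off_res[1],
            off_res[1] + short_full.shape[2],
        )
    else:
        box = _common_box(
            [(acts[-1].shape[1:], off_cnn), (short_full.shape[1:], off_res)]
        )
    # clip the anchor box to anchors whose target line exists
    a0, a1, b0, b1 = box
    n_tx, n_ty = target.shape[1], target.shape[2]
    a1 = min(a1, n_tx)  # target arrays are indexed by anchor coords directly
    b1 = min(b1, n_ty)
    if a1 <= a0 or b1 <= b0:
        raise ValueError("no calibration positions with available targets")
    box = (a0, a1, b0, b1)

    short = _crop(short_full, off_res, box)
    if is_grappa:
        cnn_out = None
        pred_native = short
    else:
        cnn_out = _crop(acts[-1], off_cnn, box)
        pred_native = cnn_out + short

    pred = _to_complex(pred_native) if is_real else pred_native
    short_c = _to_complex(short) if is_real else short
    tgt = target[:, a0:a1, b0:b1]

    n = tgt.size
    d_pred = pred - tgt
    d_short = short_c - tgt
    loss = float(np.mean(np.abs(d_pred) ** 2))
    if not is_grappa and lam:
        loss += lam * float(np.mean(np.abs(d_short) ** 2))

    G_pred = 2.0 * d_pred / n
    G_short = G_pred + (2.0 * lam * d_short / n if (not is_grappa and lam) else 0.0)

    def to_native(Gc):
        return _to_real_channels(Gc) if is_real else Gc

    grads_layers = [None] * len(weights.layers)
    dX_total = None

    def embed(G_crop, full_shape, off):
        full = np.zeros(full_shape, dtype=G_crop.dtype)
        full[
            :,
            box[0] - off[0] : box[1] - off[0],
            box[2] - off[1] : box[3] - off[1],
        ] = G_crop
        return full

    # residual path
    Gs = embed(to_native(G_short), short_full.shape, off_res)
    d_res, dX_res = _conv_valid_backward(x0, weights.residual, Gs)

    if not is_grappa:
        Gc = embed(to_native(G_pred), acts[-1].shape, off_cnn)
        G = Gc
        for li in range(len(weights.layers) - 1, -1, -1):
            if li < len(weights.layers) - 1:
                G = _leaky_relu_grad(pre[li], G, spec.c)
            dW, G = _conv_valid_backward(acts[li], weights.layers[li], G)
            grads_layers[li] = dW
        dX_total = G + dX_res
    else:
        dX_total = dX_res

    return loss, (grads_layers, d_res, dX_total), pred, tgt


# ---------------------------------------------------------------------------
# closed-form GRAPPA calibration


def fit_grappa_tikhonov(
    acs: ACSBlock,
    R: int,
    m: int,
    spec: ModelSpec,
    lambda_reg: float = 1e-3,
) -> ModelWeights:
    """Tikhonov-regularized least-squares GRAPPA calibration.

    Source patches slide over the ACS with ky taps spaced R apart; the
    target sample sits at the anchor tap position + m.  Solves
    (A^H A + mu I) w = A^H b per output coil with
    mu = lambda_reg * trace(A^H A) / n_cols.
    """
    if spec.family != "grappa":
        raise ValueError("spec.family must be 'grappa'")
    if not 1 <= m <= R - 1 and not (R == 1 and m == 0):
        raise ValueError("offset m must lie in [1, R-1]")
    nx, ny = spec.residual_kernel
    Nc, Nxacs, Nyacs = acs.data.shape
    ox, oy = (nx - 1) // 2, (ny - 1) // 2
    y_span = R * (ny - 1)
    rows_A, rows_b = [], []
    data = acs.data
    for y0 in range(0, Nyacs - y_span):
        y_t = y0 + R * oy + m
        if y_t >= Nyacs:
            continue
        taps = y0 + R * np.arange(ny)
        # (Nc, Nxacs - nx + 1, nx, ny) sliding windows along kx
        src = np.lib.stride_tricks.sliding_window_view(
            data[:, :, taps], nx, axis=1
        )  # (Nc, Nxacs-nx+1, ny, nx)
        src = src.transpose(1, 0, 3, 2)  # (pos, Nc, nx, ny)
        rows_A.append(src.reshape(src.shape[0], -1))
        rows_b.append(data[:, ox : Nxacs - nx + 1 + ox, y_t].T)  # (pos, Nc)
    if not rows_A:
        raise ValueError("ACS too small for this kernel: empty calibration set")
    A = np.concatenate(rows_A, axis=0)
    B = np.concatenate(rows_b, axis=0)
    AhA = A.conj().T @ A
    ncols = AhA.shape[0]
    mu = lambda_reg * np.trace(AhA).real / ncols
    w = np.linalg.solve(AhA + mu * np.eye(ncols), A.conj().T @ B)  # (cols, Nc)
    W = w.T.reshape(Nc, Nc, nx, ny)
    return ModelWeights(layers=[], residual=W)


# ---------------------------------------------------------------------------
# parameter accounting


def parameter_count(spec: ModelSpec) -> int:
    """Number of real-valued trainable parameters (x2 for complex kernels)."""
    factor = 2 if spec.is_complex else 1
    total = 0
    for (kx, ky), (din, dout) in zip(spec.kernel_sizes, spec.depths):
        total += factor * kx * ky * din * dout
    gx, gy = spec.residual_kernel
    io = spec.n_coils * (2 if spec.family == "rraki" else 1)
    total += factor * gx * gy * io * io
    return total
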