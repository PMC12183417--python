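"""Scan-specific supervised training on the ACS.

The fully sampled ACS is artificially undersampled into R shifted
line-pair sets (the train-validation partition, TVP): phase p contributes
the input lines TR(p) and the target lines TR(p) + m for the offset-m
model.  R-1 pair sets train the model; the remaining one is held out to
monitor validation k-space MSE, drive early stopping, and select the
best epoch.

Optimization is Adam on the real parameter vector (real and imaginary
kernel parts of complex layers are independent real parameters), with the
weighted two-term loss

    L = MSE(prediction, target) + lambda * MSE(short_prediction, target)

where the second term supervises the linear short connection alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kspace import ACSBlock
from .models import ModelSpec, ModelWeights, forward_backward

__all__ = [
    "TrainConfig",
    "TVPFoldSet",
    "TrainingDivergence",
    "normalize_acs",
    "build_tvp_pairs",
    "total_loss",
    "init_weights",
    "train_model",
]


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 1000
    patience: int = 20
    lambda_loss: float = 0.0
    seed: int = 0
    # "best": count epochs since the running-best validation MSE improved;
    # "previous": count consecutive epoch-over-epoch increases.
    monitor: str = "best"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 <= self.lambda_loss:
            raise ValueError("lambda_loss must be >= 0")
        if self.monitor not in ("best", "previous"):
            raise ValueError("monitor must be 'best' or 'previous'")


@dataclass
class TVPFoldSet:
    """The R input/target line-pair sets carved from one ACS.

    ``pairs[p-1]`` holds, for phase p in {1..R}, the 0-based input line
    indices TR(p) inside the ACS and the target indices (input + m,
    truncated to the ACS).  ``validation_phase`` selects the held-out set.
    """

    acs: ACSBlock
    R: int
    m: int
    pairs: list[tuple[np.ndarray, np.ndarray, int]] = field(default_factory=list)
    validation_phase: int = 0

    @property
    def training_pairs(self):
        return [p for p in self.pairs if p[2] != self.validation_phase]

    @property
    def validation_pair(self):
        for p in self.pairs:
            if p[2] == self.validation_phase:
                return p
        raise ValueError("validation phase not found")


def normalize_acs(acs: ACSBlock) -> tuple[ACSBlock, float]:
    """Divide by the global 2-norm over all complex samples and coils."""
    scale = float(np.linalg.norm(acs.data))
    if scale == 0.0:
        scale = 1.0
    return (
        ACSBlock(acs.data / scale, mode=acs.mode, ky_origin=acs.ky_origin),
        scale,
    )


def build_tvp_pairs(
    acs: ACSBlock, R: int, m: int, validation_phase: int | None = None
) -> TVPFoldSet:
    """Carve the R shifted line-pair sets out of one ACS for offset m.

    Phase p (1-based) contributes inputs at 0-based ACS lines
    {p-1, p-1+R, ...} and targets at input + m where that still falls
    inside the ACS.  The default validation phase is the last one (p = R).
    """
    Nyacs = acs.data.shape[2]
    if Nyacs < 2 * R:
        raise ValueError("ACS too small: need Nyacs >= 2R")
    if not 1 <= m <= R - 1 and not (R == 1 and m == 0):
        raise ValueError("offset m must lie in [1, R-1]")
    vp = R if validation_phase is None else validation_phase
    if not 1 <= vp <= R:
        raise ValueError("validation_phase must lie in [1, R]")
    pairs = []
    for p in range(1, R + 1):
        inputs = np.arange(p - 1, Nyacs, R)
        targets = inputs + m
        targets = targets[targets <= Nyacs - 1]
        pairs.append((inputs, targets, p))
    return TVPFoldSet(acs=acs, R=R, m=m, pairs=pairs, validation_phase=vp)


def total_loss(
    prediction: np.ndarray,
    short_prediction: np.ndarray,
    target: np.ndarray,
    lam: float,
) -> float:
    """MSE(pred, target) + lam * MSE(short, target); complex MSE is the
    mean squared modulus of the difference."""
    mse = float(np.mean(np.abs(prediction - target) ** 2))
    mse_s = float(np.mean(np.abs(short_prediction - target) ** 2))
    return mse + lam * mse_s


# ---------------------------------------------------------------------------
# parameters


def _fan_in(din: int, kx: int, ky: int, is_complex: bool) -> int:
    return din * kx * ky * (2 if is_complex else 1)


def init_weights(spec: ModelSpec, seed: int = 0) -> ModelWeights:
    """Zero-mean normal draws with per-layer std sqrt(2 / fan_in).

    For complex kernels the real and imaginary parts are drawn
    independently and the fan-in counts both components.
    """
    rng = np.random.default_rng(seed)

    def draw(dout, din, kx, ky):
        std = np.sqrt(2.0 / _fan_in(din, kx, ky, spec.is_complex))
        if spec.is_complex:
            return std * (
                rng.standard_normal((dout, din, kx, ky))
                + 1j * rng.standard_normal((dout, din, kx, ky))
            )
        return std * rng.standard_normal((dout, din, kx, ky))

    layers = [
        draw(dout, din, kx, ky)
        for (kx, ky), (din, dout) in zip(spec.kernel_sizes, spec.depths)
    ]
    io = spec.n_coils * (2 if spec.family == "rraki" else 1)
    gx, gy = spec.residual_kernel
    residual = draw(io, io, gx, gy)
    return ModelWeights(layers=layers, residual=residual)


def _pack(weights: ModelWeights, is_complex: bool) -> list[np.ndarray]:
    """Flatten to a list of real arrays (Wr, Wi pairs for complex)."""
    params = []
    for W in list(weights.layers) + [weights.residual]:
        if is_complex:
            params.extend([W.real.copy(), W.imag.copy()])
        else:
            params.append(W.copy())
    return params


def _unpack(params: list[np.ndarray], spec: ModelSpec) -> ModelWeights:
    n_layers = len(spec.kernel_sizes)
    arrays = []
    i = 0
    for _ in range(n_layers + 1):
        if spec.is_complex:
            arrays.append(params[i] + 1j * params[i + 1])
            i += 2
        else:
            arrays.append(params[i].copy())
            i += 1
    return ModelWeights(layers=arrays[:-1], residual=arrays[-1])


def _grads_to_real(grads, spec: ModelSpec) -> list[np.ndarray]:
    grads_layers, d_res, _ = grads
    out = []
    for g in list(grads_layers) + [d_res]:
        if spec.is_complex:
            out.extend([g.real, g.imag])
        else:
            out.append(g)
    return out


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training loop


def _batch_arrays(folds: TVPFoldSet, pair) -> tuple[np.ndarray, np.ndarray]:
    inputs, targets, _ = pair
    data = folds.acs.data
    stack = data[:, :, inputs]
    tgt = data[:, :, targets]
    return stack, tgt


def train_model(
    folds: TVPFoldSet, spec: ModelSpec, cfg: TrainConfig
) -> tuple[ModelWeights, pd.DataFrame]:
    """Adam training on the TVP pair sets with best-epoch early stopping.

    Each training pair set is one (full) batch per epoch.  After every
    epoch the validation k-space MSE (model prediction vs. held-out
    targets) is recorded; training stops at ``max_epochs`` or once the
    validation MSE has failed to improve for more than ``patience``
    consecutive epochs (``monitor='best'``; ``'previous'`` counts strict
    epoch-over-epoch increases instead).  The weights of the epoch with
    the lowest validation MSE are returned together with the per-epoch
    history (epoch, train_loss, val_mse).
    """
    if not folds.training_pairs:
        raise ValueError("need at least one training pair set")
    weights = init_weights(spec, cfg.seed)
    params = _pack(weights, spec.is_complex)
    opt = _Adam(params, cfg.learning_rate)

    batches = [_batch_arrays(folds, p) for p in folds.training_pairs]
    val_stack, val_tgt = _batch_arrays(folds, folds.validation_pair)

    best_val = np.inf
    best_params = [p.copy() for p in params]
    prev_val = np.inf
    bad = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        train_losses = []
        for stack, tgt in batches:
            w = _unpack(params, spec)
            loss, grads, _, _ = forward_backward(
                stack, tgt, w, spec, cfg.lambda_loss
            )
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.step(params, _grads_to_real(grads, spec))
            train_losses.append(loss)
        w = _unpack(params, spec)
        val_loss, _, _, _ = forward_backward(val_stack, val_tgt, w, spec, 0.0)
        if not np.isfinite(val_loss):
            raise TrainingDivergence(f"non-finite validation MSE at epoch {epoch}")
        rows.append((epoch, float(np.mean(train_losses)), val_loss))

        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in params]
        if cfg.monitor == "best":
            bad = 0 if val_loss <= best_val else bad + 1
        else:
            bad = bad + 1 if val_loss > prev_val else 0
        prev_val = val_loss
        if bad > cfg.patience:
            break

    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_mse"])
    return _unpack(best_params, spec), history


def validation_mse(
    folds: TVPFoldSet, weights: ModelWeights, spec: ModelSpec
) -> float:
    """Validation k-space MSE of a trained model on the held-out pair set."""
    stack, tgt = _batch_arrays(folds, folds.validation_pair)
    loss, _, _, _ = forward_backward(stack, tgt, weights, spec, 0.0)
    return loss
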