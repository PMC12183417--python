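"""End-to-end reconstruction glue.

Trains (or solves in closed form) one interpolation model per missing
line offset, applies each periodically to the acquired lines, merges the
predictions with the measured data, and returns the coil-combined image.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .kspace import (
    ACSBlock,
    CombinedImage,
    MultiCoilKSpace,
    combine_sos,
    kspace_to_image,
    merge_predictions,
)
from .models import ModelSpec, ModelWeights, fit_grappa_tikhonov, predict_offset
from .training import TrainConfig, build_tvp_pairs, normalize_acs, train_model

__all__ = ["train_offset_models", "reconstruct"]


def train_offset_models(
    acs: ACSBlock,
    R: int,
    spec: ModelSpec,
    cfg: TrainConfig,
    method: str = "tvp",
    lambda_reg: float = 1e-3,
) -> tuple[dict[int, ModelWeights], float]:
    """One model per offset m in {1..R-1}; returns (models, acs_scale).

    ``method='tvp'`` trains with the ACS train-validation partition;
    ``method='tikhonov'`` (GRAPPA only) uses the closed-form regularized
    least-squares calibration.
    """
    norm_acs, scale = normalize_acs(acs)
    models: dict[int, ModelWeights] = {}
    for m in range(1, R):
        if method == "tikhonov":
            if spec.family != "grappa":
                raise ValueError("closed-form calibration is GRAPPA-only")
            models[m] = fit_grappa_tikhonov(norm_acs, R, m, spec, lambda_reg)
        elif method == "tvp":
            folds = build_tvp_pairs(norm_acs, R, m)
            models[m], _ = train_model(folds, spec, replace(cfg, seed=cfg.seed + m))
        else:
            raise ValueError(f"unknown method {method!r}")
    return models, scale


def reconstruct(
    und: MultiCoilKSpace,
    acs: ACSBlock,
    spec: ModelSpec,
    cfg: TrainConfig | None = None,
    method: str = "tvp",
    lambda_reg: float = 1e-3,
) -> tuple[MultiCoilKSpace, CombinedImage]:
    """Reconstruct a uniformly undersampled scan from its ACS.

    The undersampled data are brought to the ACS normalization scale
    before the (possibly nonlinear) models are applied, and rescaled
    afterwards.  Measured lines — and integrated-mode ACS lines — always
    override predictions.
    """
    cfg = cfg or TrainConfig()
    R = und.R
    if R == 1:
        full = MultiCoilKSpace(und.data.copy(), R=1, m0=1)
        return full, combine_sos(kspace_to_image(full.data))
    models, scale = train_offset_models(
        acs, R, spec, cfg, method=method, lambda_reg=lambda_reg
    )
    und_scaled = MultiCoilKSpace(
        und.data / scale, sampled_ky=und.sampled_ky, R=R, m0=und.m0
    )
    predictions = {
        m + 1: predict_offset(und_scaled, models[m], spec, m) * scale
        for m in range(1, R)
    }
    merged = merge_predictions(und, predictions, acs=acs)
    image = combine_sos(kspace_to_image(merged.data))
    return merged, image
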