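"""Objective hyperparameter selection from the ACS alone.

Architectures are compared with exhaustive grid search combined with
K-fold cross-validation where K equals the acceleration rate R: each of
the R TVP phases serves once as the held-out validation set, every
offset model is trained on the remaining phases, and the validation
k-space MSE is pooled (averaged over offsets) into one sample per
(fold, slice).  The architecture with the lowest mean MSE is "best"; a
one-tailed Welch t-test then screens the rest, and every architecture
not significantly worse than the best joins the optimal set.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .kspace import ACSBlock
from .models import ModelSpec, parameter_count
from .training import TrainConfig, build_tvp_pairs, normalize_acs, train_model

__all__ = [
    "GridResult",
    "enumerate_grid",
    "kfold_cv",
    "welch_one_tailed",
    "select_architectures",
    "linearity_ablation",
    "ABLATION_C_GRID",
    "ABLATION_LAMBDA_GRID",
]

# published ablation grids for the LeakyReLU slope and the loss weight
ABLATION_C_GRID = (0.0, 0.01, 0.1, 0.2, 0.3, 0.5, 0.7, 0.9, 1.0)
ABLATION_LAMBDA_GRID = (0.0, 1.0)

_GRAPPA_KERNELS = ((3, 2), (5, 2), (5, 4), (5, 5), (7, 2), (7, 4), (9, 2), (9, 4))
_RAKI_FIRST = ((5, 2), (5, 4))
_RAKI_DEPTHS = (16, 8, 4)  # complex units; real networks use 2x (32, 16, 8)
_RAKI_THIRD = ((3, 2), (3, 4))
_RAKI_RESIDUAL = ((5, 2), (1, 1))


@dataclass
class GridResult:
    """Cross-validation outcome for one architecture."""

    config_id: str
    spec: ModelSpec
    samples: np.ndarray  # one pooled validation MSE per (fold, slice)
    K: int

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self.samples))


def enumerate_grid(family: str, n_coils: int = 4) -> list[ModelSpec]:
    """All candidate architectures of one family.

    GRAPPA enumerates its 8 kernel sizes; rRAKI/crRAKI enumerate
    first-layer kernel x layer-1 depth x layer-2 depth x third-layer
    kernel x residual kernel (72 configurations).
    """
    if family == "grappa":
        return [ModelSpec.grappa(n_coils, kernel=k) for k in _GRAPPA_KERNELS]
    if family in ("rraki", "crraki"):
        ctor = ModelSpec.rraki if family == "rraki" else ModelSpec.crraki
        return [
            ctor(n_coils, first=f, d1=d1, d2=d2, third=t, residual=r)
            for f, d1, d2, t, r in itertools.product(
                _RAKI_FIRST, _RAKI_DEPTHS, _RAKI_DEPTHS, _RAKI_THIRD, _RAKI_RESIDUAL
            )
        ]
    raise ValueError(f"unknown family {family!r}")


def _derive_seed(base: int, tag: str) -> int:
    return (int(base) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


def kfold_cv(
    acs: ACSBlock | list[ACSBlock],
    R: int,
    spec: ModelSpec,
    cfg: TrainConfig,
) -> GridResult:
    """K-fold (K = R) cross-validated k-space MSE of one architecture.

    For every fold p and every slice, each offset model m in {1..R-1} is
    trained with validation phase p; the best-epoch validation MSEs are
    averaged over offsets into one sample.  Seeds are derived from the
    config label and fold/slice/offset tags so results are independent of
    execution order.
    """
    slices = acs if isinstance(acs, list) else [acs]
    cid = spec.label()
    samples = []
    for p in range(1, R + 1):
        for si, block in enumerate(slices):
            norm, _ = normalize_acs(block)
            per_offset = []
            for m in range(1, R):
                folds = build_tvp_pairs(norm, R, m, validation_phase=p)
                # seed depends on config/fold/offset only, so identical
                # slices yield identical samples and results are
                # independent of execution order
                sub = replace(cfg, seed=_derive_seed(cfg.seed, f"{cid}|{p}|{m}"))
                try:
                    _, history = train_model(folds, spec, sub)
                except Exception as err:
                    raise RuntimeError(
                        f"training diverged for {cid}, fold {p}, slice {si}, "
                        f"offset {m}"
                    ) from err
                per_offset.append(float(history["val_mse"].min()))
            samples.append(float(np.mean(per_offset)))
    return GridResult(
        config_id=cid, spec=spec, samples=np.asarray(samples), K=R
    )


def welch_one_tailed(a, b) -> float:
    """One-tailed Welch t-test p-value for mean(a) < mean(b).

    Uses the unequal-variance statistic with Satterthwaite degrees of
    freedom.
    """
    res = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False,
                          alternative="less")
    return float(res.pvalue)


def select_architectures(
    results: list[GridResult], alpha: float = 0.05
) -> tuple[str, list[str]]:
    """Best architecture plus the set not significantly worse than it.

    Best = argmin of mean validation MSE (ties broken toward fewer
    parameters).  A config joins the optimal set when the one-tailed Welch
    test of best < config yields p >= alpha.  The raw p-values are
    available via :func:`welch_one_tailed` for the alternative reading.
    """
    if not results:
        raise ValueError("no grid results supplied")
    ordered = sorted(
        results, key=lambda r: (r.mean_mse, parameter_count(r.spec), r.config_id)
    )
    best = ordered[0]
    optimal = [best.config_id]
    for r in results:
        if r.config_id == best.config_id:
            continue
        if welch_one_tailed(best.samples, r.samples) >= alpha:
            optimal.append(r.config_id)
    return best.config_id, optimal


def linearity_ablation(
    acs: ACSBlock | list[ACSBlock],
    R: int,
    spec_base: ModelSpec,
    c_grid=ABLATION_C_GRID,
    lambda_grid=ABLATION_LAMBDA_GRID,
    cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Cross-validated sweep over the LeakyReLU slope c and loss weight λ.

    Returns one row per (c, λ) with the mean validation MSE, a flag on the
    row minimizing it, and the one-tailed Welch p-value of best < row.
    """
    cfg = cfg or TrainConfig()
    rows = []
    for c in c_grid:
        for lam in lambda_grid:
            spec = spec_base.with_linearity(float(c))
            res = kfold_cv(acs, R, spec, replace(cfg, lambda_loss=float(lam)))
            rows.append({"c": float(c), "lambda": float(lam),
                         "mean_mse": res.mean_mse, "samples": res.samples})
    df = pd.DataFrame(rows)
    best_i = int(df["mean_mse"].idxmin())
    df["is_best"] = False
    df.loc[best_i, "is_best"] = True
    best_samples = df.loc[best_i, "samples"]
    df["p_vs_best"] = [
        1.0 if i == best_i else welch_one_tailed(best_samples, s)
        for i, s in enumerate(df["samples"])
    ]
    return df.drop(columns=["samples"]).assign(
        samples=[np.asarray(s) for s in df["samples"]]
    )
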