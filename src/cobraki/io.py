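"""File formats: fastMRI-dialect HDF5, internal simulation containers,
weight serialization, and image output (PNG / NIfTI)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .kspace import ACSBlock, MultiCoilKSpace
from .models import ModelSpec, ModelWeights

__all__ = [
    "read_fastmri_h5",
    "write_fastmri_h5",
    "save_simulation",
    "load_simulation",
    "save_weights",
    "load_weights",
    "save_png",
    "save_nifti",
]


class FormatError(ValueError):
    pass


def read_fastmri_h5(path) -> list[MultiCoilKSpace]:
    """Read a fastMRI-dialect file: complex `kspace` of [slice, coil, kx, ky]."""
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise FormatError(f"{path}: no 'kspace' dataset")
        ds = f["kspace"]
        if not np.issubdtype(ds.dtype, np.complexfloating):
            raise FormatError(f"{path}: 'kspace' is not complex-valued")
        if ds.ndim != 4:
            raise FormatError(f"{path}: expected [slice, coil, kx, ky]")
        arr = ds[()]
    return [MultiCoilKSpace(arr[s], R=1, m0=1) for s in range(arr.shape[0])]


def write_fastmri_h5(path, kspace: np.ndarray) -> None:
    kspace = np.asarray(kspace)
    if kspace.ndim != 4:
        raise FormatError("expected [slice, coil, kx, ky]")
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.astype(np.complex64))


def save_simulation(
    path,
    kspaces: list[MultiCoilKSpace],
    acs: ACSBlock | None = None,
    echo_times_ms=None,
    seed: int | None = None,
) -> None:
    """Internal container: `kspace` [echo, coil, kx, ky] (+ optional `acs`)."""
    data = np.stack([k.data for k in kspaces])
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=data.astype(np.complex128))
        if acs is not None:
            d = f.create_dataset("acs", data=acs.data.astype(np.complex128))
            d.attrs["mode"] = acs.mode
            d.attrs["ky_origin"] = acs.ky_origin
        if echo_times_ms is not None:
            f.attrs["echo_times_ms"] = np.asarray(echo_times_ms, dtype=float)
        if seed is not None:
            f.attrs["seed"] = int(seed)


def load_simulation(path):
    with h5py.File(path, "r") as f:
        if "kspace" not in f:
            raise FormatError(f"{path}: no 'kspace' dataset")
        arr = f["kspace"][()]
        kspaces = [MultiCoilKSpace(arr[e], R=1, m0=1) for e in range(arr.shape[0])]
        acs = None
        if "acs" in f:
            d = f["acs"]
            acs = ACSBlock(
                d[()], mode=str(d.attrs["mode"]), ky_origin=int(d.attrs["ky_origin"])
            )
        echo_times = f.attrs.get("echo_times_ms")
        seed = f.attrs.get("seed")
    return kspaces, acs, echo_times, seed


def save_weights(path, weights: ModelWeights, spec: ModelSpec) -> None:
    with h5py.File(path, "w") as f:
        for i, W in enumerate(weights.layers):
            f.create_dataset(f"layer_{i}", data=W)
        f.create_dataset("residual", data=weights.residual)
        f.attrs["spec"] = json.dumps(
            {
                "family": spec.family,
                "n_coils": spec.n_coils,
                "kernel_sizes": spec.kernel_sizes,
                "depths": spec.depths,
                "residual_kernel": spec.residual_kernel,
                "c": spec.c,
            }
        )


def load_weights(path) -> tuple[ModelWeights, ModelSpec]:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["spec"])
        layers = []
        i = 0
        while f"layer_{i}" in f:
            layers.append(f[f"layer_{i}"][()])
            i += 1
        residual = f["residual"][()]
    spec = ModelSpec(
        family=meta["family"],
        n_coils=meta["n_coils"],
        kernel_sizes=tuple(tuple(k) for k in meta["kernel_sizes"]),
        depths=tuple(tuple(d) for d in meta["depths"]),
        residual_kernel=tuple(meta["residual_kernel"]),
        c=meta["c"],
    )
    return ModelWeights(layers=layers, residual=residual), spec


def save_png(path, image: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, np.asarray(image, dtype=float), cmap="gray")


def save_nifti(path, image: np.ndarray) -> None:
    import nibabel as nib

    img = np.asarray(image, dtype=np.float32)
    nib.save(nib.Nifti1Image(img[..., None], affine=np.eye(4)), str(path))


def _ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
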