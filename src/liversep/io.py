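"""NIfTI-1 and sidecar I/O.

Complex echo stacks are stored as a 5-D NIfTI volume of shape
(x, y, z, echo, 2) holding the real and imaginary parts, with the
acquisition metadata in a JSON sidecar next to the image file; scalar
maps are plain 3-D volumes.  Affines carry the voxel size (RAS)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import AcquisitionParams
from .series import EchoSeries

__all__ = ["write_echo_series", "read_echo_series", "write_volume",
           "read_volume", "sidecar_path"]


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[:-len(suf)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_echo_series(series: EchoSeries, path) -> Path:
    path = Path(path)
    stacked = np.stack([series.data.real, series.data.imag], axis=-1)
    img = nib.Nifti1Image(stacked.astype(np.float64), _affine(series.acq.voxel_size))
    nib.save(img, path)
    with open(sidecar_path(path), "w") as fh:
        json.dump(series.acq.to_dict(), fh, indent=2)
    return path


def read_echo_series(path) -> EchoSeries:
    path = Path(path)
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {path}: {sc}")
    with open(sc) as fh:
        acq = AcquisitionParams.from_dict(json.load(fh))
    arr = np.asarray(nib.load(path).dataobj)
    if arr.ndim != 5 or arr.shape[-1] != 2:
        raise ValueError(f"expected (x,y,z,echo,2) real/imaginary stack, got {arr.shape}")
    if arr.shape[3] != acq.n_echoes:
        raise ValueError(f"file has {arr.shape[3]} echoes, sidecar says {acq.n_echoes}")
    return EchoSeries(data=arr[..., 0] + 1j * arr[..., 1], acq=acq)


def write_volume(volume: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), _affine(voxel_size))
    nib.save(img, path)
    return path


def read_volume(path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj)
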