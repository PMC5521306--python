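"""Volumetric time-series container and NIfTI-1 I/O.

The whole pipeline operates on reconstructed voxel-space oxyhemoglobin
(ΔHbO) images: a 4-D scalar field (x, y, z, t) with a diagonal world
affine (MNI-style mm) and an explicit sampling rate.  The sampling rate
is stored in the NIfTI header's time-dimension pixel size (pixdim[4],
seconds per frame), so files round-trip without sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumetricTimeSeries",
    "read_volume",
    "write_volume",
    "read_image",
    "write_image",
    "voxel_centers_world",
]


@dataclass
class VolumetricTimeSeries:
    """4-D ΔHbO recording: ``data[x, y, z, t]`` plus geometry and rate.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (mm).  Only diagonal (axis-aligned) affines
        are produced by this package.
    rate : float
        Sampling rate in Hz.
    mask : ndarray of bool, shape (X, Y, Z), optional
        Field-of-view mask; defaults to all-true.
    band : tuple (low, high) or None
        Pass band (Hz) of the last bandpass applied, if any.  Used to
        warn on aliasing at downsampling time.
    """

    data: np.ndarray
    affine: np.ndarray
    rate: float
    mask: np.ndarray = None
    band: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (x, y, z, t), got ndim={self.data.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.rate > 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial shape of data")

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of a voxel, from the affine diagonal."""
        return np.abs(np.diag(self.affine)[:3])

    @property
    def duration_s(self) -> float:
        return self.n_timepoints / self.rate

    def with_data(self, data: np.ndarray, **changes) -> "VolumetricTimeSeries":
        """Copy of this series with new data (geometry preserved)."""
        return replace(self, data=data, **changes)

    def flat(self) -> np.ndarray:
        """View of the data as (voxels, time), C-order spatial flattening."""
        return self.data.reshape(-1, self.n_timepoints)


def voxel_centers_world(spatial_shape, affine) -> np.ndarray:
    """World-mm coordinates of every voxel center, shape (V, 3), C order."""
    idx = np.indices(spatial_shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def write_volume(series: VolumetricTimeSeries, path) -> None:
    """Write a 4-D series as NIfTI-1, rate encoded as pixdim[4] = 1/rate."""
    img = nib.Nifti1Image(np.asarray(series.data), series.affine)
    zooms = tuple(series.voxel_size) + (1.0 / series.rate,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_volume(path) -> VolumetricTimeSeries:
    """Read a 4-D NIfTI-1 file into a :class:`VolumetricTimeSeries`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(
            f"{path.name}: expected a 4-D time series, got {data.ndim}-D data"
        )
    zooms = img.header.get_zooms()
    if len(zooms) < 4 or zooms[3] <= 0:
        raise ValueError(f"{path.name}: time-dimension pixel size (pixdim[4]) missing or non-positive")
    return VolumetricTimeSeries(data=data, affine=img.affine, rate=1.0 / float(zooms[3]))


def write_image(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3-D scalar field (e.g. sensitivity, mask, z-map) as NIfTI-1."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype in (np.int64, np.int32):
        arr = arr.astype(np.int16)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))


def read_image(path):
    """Read a 3-D NIfTI-1 file; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{Path(path).name}: expected a 3-D image, got {data.ndim}-D")
    return data, img.affine
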