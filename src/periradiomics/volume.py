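"""3D volume container and NIfTI/DICOM I/O.

Arrays are indexed ``[z, y, x]`` (slice, row, column) and all physical
metadata -- ``spacing_mm`` and ``origin_mm`` -- follow the same (z, y, x)
axis order.  SimpleITK stores spacing/origin as (x, y, z), so the two are
reversed at the I/O boundary and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = ["VolumeImage", "read_volume", "write_volume", "read_mask", "write_mask"]


@dataclass
class VolumeImage:
    """A 3D scalar grid (CT Hounsfield units) with physical geometry.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Voxel intensities in HU (or any scalar after normalization).
    spacing_mm : tuple of 3 floats
        Voxel size along (z, y, x), strictly positive.
    origin_mm : tuple of 3 floats
        World coordinate of voxel (0, 0, 0) along (z, y, x).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(self.values)
        img.SetSpacing(tuple(reversed(self.spacing_mm)))
        img.SetOrigin(tuple(reversed(self.origin_mm)))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VolumeImage":
        return cls(
            values=sitk.GetArrayFromImage(img),
            spacing_mm=tuple(reversed(img.GetSpacing())),
            origin_mm=tuple(reversed(img.GetOrigin())),
        )


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read a NIfTI file, or a DICOM series if ``path`` is a directory."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        reader = sitk.ImageSeriesReader()
        names = reader.GetGDCMSeriesFileNames(path)
        if not names:
            raise IOError(f"no DICOM series found in directory {path!r}")
        reader.SetFileNames(names)
        img = reader.Execute()
    else:
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:  # corrupt / unreadable
            raise IOError(f"could not read volume from {path!r}: {exc}") from exc
    if img.GetDimension() == 4 and img.GetSize()[3] == 1:
        img = img[:, :, :, 0]
    return VolumeImage.from_sitk(img)


def write_volume(vol: VolumeImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI (.nii / .nii.gz inferred from extension)."""
    sitk.WriteImage(vol.to_sitk(), os.fspath(path))


def write_mask(mask: np.ndarray, spacing_mm, path: str | os.PathLike,
               origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write a binary mask as an unsigned 8-bit NIfTI with 0/1 coding."""
    arr = np.asarray(mask).astype(np.uint8)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    write_volume(VolumeImage(arr, spacing_mm, origin_mm), path)


def read_mask(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a binary mask; returns (bool array, spacing_mm)."""
    vol = read_volume(path)
    return vol.values > 0, vol.spacing_mm
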