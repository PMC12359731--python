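"""Peritumoral region-of-interest geometry.

Three nested ROIs are used throughout:

* **GTV** -- gross tumor volume, the segmented nodule mask (an input here).
* **GPTV** -- gross peritumoral tumor volume, the GTV dilated outward by a
  physical margin (default 5 mm).
* **GPR** -- gross peritumoral region, the shell ``GPTV \\ GTV``.

Dilation is spacing-aware and exact: a voxel belongs to the dilated mask
iff its center lies within the Euclidean margin (in mm) of some foreground
voxel center, computed with an exact Euclidean distance transform rather
than iterated structuring elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RoiTriplet", "dilate_mask", "build_roi_triplet", "pad_for_margin"]

_EPS = 1e-9


@dataclass
class RoiTriplet:
    """GTV/GPTV/GPR binary masks sharing one voxel grid."""

    gtv: np.ndarray
    gptv: np.ndarray
    gpr: np.ndarray
    margin_mm: float = 5.0

    def __post_init__(self) -> None:
        self.gtv = np.asarray(self.gtv, bool)
        self.gptv = np.asarray(self.gptv, bool)
        self.gpr = np.asarray(self.gpr, bool)
        if not (self.gtv.shape == self.gptv.shape == self.gpr.shape):
            raise ValueError("GTV/GPTV/GPR must share one grid")
        if (self.gtv & ~self.gptv).any():
            raise ValueError("GTV must be a subset of GPTV")
        if (self.gpr != (self.gptv & ~self.gtv)).any():
            raise ValueError("GPR must equal GPTV minus GTV")


def dilate_mask(mask: np.ndarray, spacing_mm, margin_mm: float) -> np.ndarray:
    """Dilate a binary mask by a physical margin (mm).

    Includes every voxel whose center is within ``margin_mm`` Euclidean
    distance of a foreground voxel center.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot dilate an empty mask")
    if margin_mm <= 0:
        raise ValueError(f"margin must be positive, got {margin_mm}")
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing_mm)
    return mask | (dist <= margin_mm + _EPS)


def pad_for_margin(values: np.ndarray, mask: np.ndarray, spacing_mm,
                   margin_mm: float, fill: float = -1024.0):
    """Pad volume and mask so an outward dilation cannot hit the grid edge.

    The image is padded with background HU (air, -1024 by default); the
    mask is padded with zeros.  Returns (values, mask, pad_voxels).
    """
    pad = tuple(int(np.ceil(margin_mm / s)) + 1 for s in spacing_mm)
    widths = [(p, p) for p in pad]
    return (
        np.pad(np.asarray(values), widths, constant_values=fill),
        np.pad(np.asarray(mask, bool), widths, constant_values=False),
        pad,
    )


def build_roi_triplet(gtv_mask: np.ndarray, spacing_mm, margin_mm: float = 5.0,
                      lung_mask: np.ndarray | None = None) -> RoiTriplet:
    """Construct GTV/GPTV/GPR from a nodule mask.

    If the dilated region reaches the grid boundary a warning is issued
    (the caller should pad with :func:`pad_for_margin`); the margin is
    never silently truncated without that warning.

    Dilation is unrestricted Euclidean by default; pass ``lung_mask`` to
    exclude non-lung voxels (chest wall, mediastinum) from the
    peritumoral region while always keeping the GTV itself.
    """
    gtv = np.asarray(gtv_mask, bool)
    if not gtv.any():
        raise ValueError("GTV mask is empty")
    gptv = dilate_mask(gtv, spacing_mm, margin_mm)
    if lung_mask is not None:
        gptv &= np.asarray(lung_mask, bool) | gtv
    faces = [gptv[0], gptv[-1], gptv[:, 0], gptv[:, -1], gptv[:, :, 0], gptv[:, :, -1]]
    if any(f.any() for f in faces):
        warnings.warn(
            "dilated GPTV reaches the grid boundary; the peritumoral margin "
            "is clipped -- pad the volume with pad_for_margin() first",
            stacklevel=2,
        )
    return RoiTriplet(gtv=gtv, gptv=gptv, gpr=gptv & ~gtv, margin_mm=float(margin_mm))
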