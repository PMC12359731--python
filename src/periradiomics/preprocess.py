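"""Intensity normalization, isotropic resampling, gray-level discretization.

The preprocessing chain mirrors standard CT-radiomics practice for lung
nodules: lung-window intensity normalization ``(HU - level) / width`` with
level -600 / width 1500, B-spline resampling to 1 mm isotropic voxels
(nearest-neighbor for masks), and fixed-bin-width discretization
(binWidth 25 HU) anchored at the ROI minimum.

Discretization operates on original HU values inside the ROI: a 25-HU bin
width applied to window-normalized values in [-0.5, 0.5] would collapse
every ROI to a single gray level.  The window normalization is kept as an
explicit, separately callable step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .volume import VolumeImage

__all__ = [
    "PreprocessConfig",
    "normalize_intensity",
    "resample",
    "resample_mask",
    "discretize",
    "discretize_volume",
]


@dataclass
class PreprocessConfig:
    """Normalization / resampling / discretization parameters.

    Defaults follow the lung-window convention: level -600 HU, width
    1500 HU, 1 mm isotropic target grid, 25 HU bin width.
    """

    window_level: float = -600.0
    window_width: float = 1500.0
    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be > 0")


def normalize_intensity(img: VolumeImage, cfg: PreprocessConfig | None = None) -> VolumeImage:
    """Lung-window normalization: ``(HU - window_level) / window_width``."""
    cfg = cfg or PreprocessConfig()
    out = (img.values.astype(float) - cfg.window_level) / cfg.window_width
    return VolumeImage(out, img.spacing_mm, img.origin_mm)


def _resample_sitk(img: VolumeImage, target_zyx, interpolator, default_value: float):
    src = img.to_sitk()
    spacing_xyz = tuple(reversed(target_zyx))
    size_in = np.array(src.GetSize(), float)          # (x, y, z)
    spc_in = np.array(src.GetSpacing(), float)
    size_out = np.maximum(1, np.ceil(size_in * spc_in / np.array(spacing_xyz)).astype(int))
    res = sitk.Resample(
        src,
        [int(s) for s in size_out],
        sitk.Transform(),
        interpolator,
        src.GetOrigin(),
        spacing_xyz,
        src.GetDirection(),
        default_value,
        sitk.sitkFloat64 if interpolator != sitk.sitkNearestNeighbor else src.GetPixelID(),
    )
    return VolumeImage.from_sitk(res)


def resample(img: VolumeImage, cfg: PreprocessConfig | None = None) -> VolumeImage:
    """Resample intensities to the target grid with cubic B-spline interpolation.

    The output grid is anchored at the input origin and covers the input
    bounding box; out-of-support voxels are filled with -1024 HU.
    """
    cfg = cfg or PreprocessConfig()
    return _resample_sitk(img, cfg.target_spacing_mm, sitk.sitkBSpline, -1024.0)


def resample_mask(mask: np.ndarray, spacing_mm, cfg: PreprocessConfig | None = None,
                  origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Resample a binary mask with nearest-neighbor interpolation (stays binary)."""
    cfg = cfg or PreprocessConfig()
    vol = VolumeImage(np.asarray(mask, np.uint8), spacing_mm, origin_mm)
    out = _resample_sitk(vol, cfg.target_spacing_mm, sitk.sitkNearestNeighbor, 0.0)
    return out.values > 0


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization anchored at the ROI minimum.

    ``level(x) = floor((x - min) / bin_width) + 1`` so levels run 1..N_g and
    the mapping is invariant to global intensity shifts.
    """
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty ROI sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    return np.floor((values - values.min()) / bin_width).astype(np.int64) + 1


def discretize_volume(values: np.ndarray, mask: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Discretize intensities inside ``mask``; 0 marks outside-ROI voxels.

    Returns (level volume, N_g).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    levels = np.zeros(mask.shape, np.int64)
    levels[mask] = discretize(np.asarray(values, float)[mask], bin_width)
    return levels, int(levels.max())
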