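"""Image filter bank: wavelet sub-bands and Laplacian-of-Gaussian.

Derived images multiply the non-shape feature count: each sub-band /
LoG image is fed through the first-order and texture families with a
filter-prefixed feature name (e.g. ``wavelet-HLL_glcm_Contrast``).
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import ndimage

__all__ = ["wavelet_subbands", "log_images", "filter_bank"]


def wavelet_subbands(values: np.ndarray, wavelet: str = "coif1") -> dict[str, np.ndarray]:
    """Single-level stationary (undecimated) 3D wavelet decomposition.

    Returns the 8 same-size sub-bands keyed ``wavelet-LLL`` .. ``wavelet-HHH``
    (L = approximation, H = detail, in (z, y, x) axis order).
    """
    values = np.asarray(values, float)
    # swt needs even dims; pad at the high end and crop after
    pad = [(0, n % 2) for n in values.shape]
    padded = np.pad(values, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1, start_level=0)[0]
    out = {}
    crop = tuple(slice(0, n) for n in values.shape)
    for key, arr in coeffs.items():
        name = "wavelet-" + key.replace("a", "L").replace("d", "H").upper()
        out[name] = arr[crop]
    return out


def log_images(values: np.ndarray, spacing_mm, sigmas_mm=(1.0, 2.0)) -> dict[str, np.ndarray]:
    """Laplacian-of-Gaussian filtered images at physical sigmas (mm)."""
    values = np.asarray(values, float)
    spacing = np.asarray(spacing_mm, float)
    out = {}
    for s in sigmas_mm:
        if s <= 0:
            raise ValueError(f"LoG sigma must be positive, got {s}")
        out[f"log-sigma-{s:g}mm"] = ndimage.gaussian_laplace(values, sigma=s / spacing)
    return out


def filter_bank(values: np.ndarray, spacing_mm, wavelet: bool = True,
                log_sigmas_mm=(1.0, 2.0)) -> dict[str, np.ndarray]:
    """All enabled derived images, keyed by filter name."""
    out: dict[str, np.ndarray] = {}
    if wavelet:
        out.update(wavelet_subbands(values))
    if log_sigmas_mm:
        out.update(log_images(values, spacing_mm, log_sigmas_mm))
    return out
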