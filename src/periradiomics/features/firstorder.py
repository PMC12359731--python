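"""First-order (intensity histogram) features.

Entropy and uniformity are computed on the fixed-bin-width discretized
histogram (default 25 HU), log base 2; everything else on raw ROI values.
Variance uses the population (N) denominator and kurtosis is the
non-excess (Pearson) form, the conventions usual in radiomics toolkits.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import discretize

__all__ = ["first_order_features"]


def first_order_features(values: np.ndarray, bin_width: float = 25.0) -> dict[str, float]:
    x = np.asarray(values, float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    centered = x - mean
    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(float) / n
    p_nz = p[p > 0]
    feats = {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Variance": var,
        "Skewness": float(np.mean(centered**3) / sd**3) if sd > 0 else 0.0,
        "Kurtosis": float(np.mean(centered**4) / var**2) if var > 0 else 0.0,
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Percentile10": float(np.percentile(x, 10)),
        "Percentile90": float(np.percentile(x, 90)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(centered))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Uniformity": float(np.sum(p_nz**2)),
    }
    return feats
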