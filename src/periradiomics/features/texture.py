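"""Texture features computed from the gray-level matrices.

Feature definitions follow the standard radiomics conventions for each
family; per-direction families (GLCM, GLRLM) average the feature value
over the 13 3D directions.  Degenerate ROIs (a single voxel, or a single
gray level with no valid pairs) return the documented fallback values:
0 for most features, 1 for GLCM correlation.
"""

from __future__ import annotations

import numpy as np

from ._matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
]

_EPS = np.finfo(float).eps


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((I * p).sum())
    sigma2 = float(((I - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)

    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])

    pnz = p[p > 0]
    hxy = float(-(pnz * np.log2(pnz)).sum())
    px_nz = px[px > 0]
    hx = float(-(px_nz * np.log2(px_nz)).sum())
    pxpy = np.outer(px, px)
    mask = p > 0
    hxy1 = float(-(p[mask] * np.log2(pxpy[mask] + _EPS)).sum())
    m2 = pxpy > 0
    hxy2 = float(-(pxpy[m2] * np.log2(pxpy[m2])).sum())

    corr = float(((I * J * p).sum() - mu * mu) / sigma2) if sigma2 > 0 else 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    offdiag = np.abs(I - J) > 0
    inv_var = float((p[offdiag] / (I - J)[offdiag] ** 2).sum())

    dk_nz = p_diff[p_diff > 0]
    sk_nz = p_sum[p_sum > 0]
    diff_avg = float((k_diff * p_diff).sum())
    return {
        "Autocorrelation": float((I * J * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float((((I + J) - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float((((I + J) - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float((((I + J) - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((I - J) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(dk_nz * np.log2(dk_nz)).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1 + (I - J) ** 2)).sum()),
        "Id": float((p / (1 + np.abs(I - J))).sum()),
        "Idmn": float((p / (1 + ((I - J) / ng) ** 2)).sum()),
        "Idn": float((p / (1 + np.abs(I - J) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(sk_nz * np.log2(sk_nz)).sum()),
        "SumSquares": sigma2,
    }


_GLCM_DEGENERATE = {name: 0.0 for name in _glcm_features_single(np.ones((1, 1)))}
_GLCM_DEGENERATE["Correlation"] = 1.0


def glcm_features(levels: np.ndarray, n_levels: int, distance: int = 1) -> dict[str, float]:
    """Co-occurrence features averaged over the 13 3D directions."""
    mats = glcm_matrices(levels, n_levels, distance)
    if not mats:  # no voxel pair in any direction
        return dict(_GLCM_DEGENERATE)
    per_dir = [_glcm_features_single(p) for p in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _rl_features_single(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, nr = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nr + 1)[None, :]
    nz = mat.sum()
    p = mat / nz
    r_i = mat.sum(axis=1)  # per gray level
    r_j = mat.sum(axis=0)  # per run length
    mu_i = float((i[:, 0] * r_i / nz).sum())
    p_nz = p[p > 0]
    return {
        "ShortRunEmphasis": float((mat / j**2).sum() / nz),
        "LongRunEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((r_i**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((r_i**2).sum() / nz**2),
        "RunLengthNonUniformity": float((r_j**2).sum() / nz),
        "RunLengthNonUniformityNormalized": float((r_j**2).sum() / nz**2),
        "RunPercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (j - float((j * p).sum())) ** 2).sum()),
        "RunEntropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "LowGrayLevelRunEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelRunEmphasis": float((mat * i**2).sum() / nz),
        "ShortRunLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "ShortRunHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LongRunLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LongRunHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }


def glrlm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Run-length features averaged over the 13 3D directions."""
    n_voxels = int((np.asarray(levels) > 0).sum())
    mats = glrlm_matrices(levels, n_levels)
    per_dir = [_rl_features_single(m, n_voxels) for m in mats if m.sum() > 0]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


_SZ_RENAME = {
    "ShortRunEmphasis": "SmallAreaEmphasis",
    "LongRunEmphasis": "LargeAreaEmphasis",
    "RunLengthNonUniformity": "SizeZoneNonUniformity",
    "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "RunPercentage": "ZonePercentage",
    "RunVariance": "ZoneVariance",
    "RunEntropy": "ZoneEntropy",
    "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
    "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
    "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
}


def glszm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Size-zone features (26-connected zones); same functional forms as
    run-length features with runs replaced by zones."""
    n_voxels = int((np.asarray(levels) > 0).sum())
    mat = glszm_matrix(levels, n_levels)
    base = _rl_features_single(mat, n_voxels)
    return {_SZ_RENAME.get(k, k): v for k, v in base.items()}


def gldm_features(levels: np.ndarray, n_levels: int, alpha: int = 0) -> dict[str, float]:
    """Dependence-matrix features (alpha = 0: equal-level dependence)."""
    mat = gldm_matrix(levels, n_levels, alpha)
    ng, nd = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    nz = mat.sum()
    p = mat / nz
    d_i = mat.sum(axis=1)
    d_j = mat.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    p_nz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((mat / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((mat * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((d_i**2).sum() / nz),
        "DependenceNonUniformity": float((d_j**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((d_j**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "LowGrayLevelEmphasis": float((mat / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((mat * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((mat / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((mat * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((mat * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((mat * i**2 * j**2).sum() / nz),
    }


def ngtdm_features(levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """Neighboring gray-tone difference features (coarseness, contrast,
    busyness, complexity, strength)."""
    n_i, s_i = ngtdm_table(levels, n_levels)
    nvp = n_i.sum()
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    coarseness = float(1.0 / max((p_i * s_i).sum(), _EPS))
    coarseness = min(coarseness, 1e6)

    if ngp > 1:
        ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
        pi, pj = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        si, sj = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        contrast = float(
            (pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp
        )
        denom = float(np.abs(ii * pi - jj * pj).sum())
        busyness = float((p_i * s_i).sum() / denom) if denom > 0 else 0.0
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / nvp)
        s_tot = s_i.sum()
        strength = float(((pi + pj) * (ii - jj) ** 2).sum() / s_tot) if s_tot > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
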