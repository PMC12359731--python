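"""Gray-level texture matrix builders (GLCM, GLRLM, GLSZM, GLDM, NGTDM).

All builders take a 3D integer *level volume* in which voxels inside the
ROI carry gray levels ``1..n_levels`` and voxels outside the ROI are 0,
exactly as produced by :func:`periradiomics.preprocess.discretize_volume`.

Conventions (stated here once, used consistently by the feature layer):

* 3D neighborhoods are the 26-connected ones; co-occurrences, runs and
  dependencies are evaluated along the 13 unique 3D directions at
  Chebyshev distance ``distance`` (default 1).
* GLCMs are symmetrized (``P + P^T``) and normalized per direction.
* GLSZM zones are 26-connected components of equal gray level.
* GLDM dependence uses tolerance alpha = 0 (equal levels); the recorded
  dependence *size* is the number of dependent neighbors plus one (the
  center voxel), so column ``j`` corresponds to size ``j`` in 1..27.
* NGTDM compares each voxel with the mean level of its in-ROI neighbors;
  edge voxels use whatever neighbors are available.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]

OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)
# one representative per +/- pair: first nonzero component positive
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    off for off in OFFSETS_26 if off > (0, 0, 0)
)


def _shifted_views(arr: np.ndarray, off):
    """Views of ``arr`` at x and x+off over the overlapping region."""
    sl_a, sl_b = [], []
    for n, o in zip(arr.shape, off):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def glcm_matrices(levels: np.ndarray, n_levels: int, distance: int = 1) -> list[np.ndarray]:
    """Symmetrized, normalized co-occurrence matrix per direction.

    Directions with no valid voxel pair are omitted.
    """
    levels = np.asarray(levels)
    out = []
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        a, b = _shifted_views(levels, off)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        i = a[valid] - 1
        j = b[valid] - 1
        counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
        p = counts.reshape(n_levels, n_levels).astype(float)
        p = p + p.T
        out.append(p / p.sum())
    return out


def glrlm_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Run-length count matrix (level x run length) per direction."""
    levels = np.asarray(levels)
    in_roi = levels > 0
    max_run = int(np.ceil(np.linalg.norm(levels.shape)))  # safe upper bound in steps
    out = []
    for d in DIRECTIONS_13:
        # same[x] <=> x and x+d both in ROI with equal level
        same = np.zeros(levels.shape, bool)
        a, b = _shifted_views(levels, d)
        sa, _ = _shifted_views(same, d)
        sa[...] = (a > 0) & (a == b)
        # chain[x] = number of consecutive 'same' links starting at x,
        # i.e. the fixpoint of chain[x] = same[x] ? chain[x+d] + 1 : 0
        chain = np.zeros(levels.shape, np.int64)
        for _ in range(max_run):
            nxt = np.zeros_like(chain)          # nxt[x] = chain[x+d]
            na, _ = _shifted_views(nxt, d)
            _, cb = _shifted_views(chain, d)
            na[...] = cb
            new = np.where(same, nxt + 1, 0)
            if (new == chain).all():
                break
            chain = new
        # run starts: in ROI with no equal-level predecessor at x-d,
        # i.e. pred_same[x] = same[x-d] is False
        pred_same = np.zeros(levels.shape, bool)
        _, pb = _shifted_views(pred_same, d)
        sm_a, _ = _shifted_views(same, d)
        pb[...] = sm_a
        starts = in_roi & ~pred_same
        run_len = chain[starts] + 1
        lev = levels[starts] - 1
        width = int(run_len.max())
        mat = np.zeros((n_levels, width), float)
        np.add.at(mat, (lev, run_len - 1), 1.0)
        out.append(mat)
    return out


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone count matrix (level x zone size), zones 26-connected."""
    levels = np.asarray(levels)
    rows = []
    max_size = 1
    for g in range(1, n_levels + 1):
        lab, nz = ndimage.label(levels == g, structure=_STRUCT26)
        if nz == 0:
            rows.append(np.zeros(0))
            continue
        sizes = np.bincount(lab.ravel())[1:]
        counts = np.bincount(sizes)  # counts[s] = zones of size s
        rows.append(counts)
        max_size = max(max_size, len(counts) - 1)
    mat = np.zeros((n_levels, max_size), float)
    for g, counts in enumerate(rows):
        if len(counts) > 1:
            mat[g, : len(counts) - 1] = counts[1:]
    return mat


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix (level x dependence size).

    A neighbor is *dependent* when ``|level - center level| <= alpha``;
    dependence size = dependent neighbor count + 1 (the center), so the
    matrix has 27 columns for a 26-neighborhood.
    """
    levels = np.asarray(levels)
    in_roi = levels > 0
    dep = np.zeros(levels.shape, np.int64)
    for off in OFFSETS_26:
        a, b = _shifted_views(levels, off)
        da, _ = _shifted_views(dep, off)
        da += ((b > 0) & (a > 0) & (np.abs(a - b) <= alpha)).astype(np.int64)
    size = dep[in_roi] + 1
    lev = levels[in_roi] - 1
    mat = np.zeros((n_levels, 27), float)
    np.add.at(mat, (lev, size - 1), 1.0)
    return mat[:, : int(size.max())]


def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighborhood gray-tone difference table.

    Returns ``(n_i, s_i)`` for levels ``i = 1..n_levels``: the voxel count
    per level and the summed absolute difference between each voxel's
    level and the average level of its in-ROI 26-neighbors.
    """
    levels = np.asarray(levels)
    in_roi = levels > 0
    nbr_sum = np.zeros(levels.shape, float)
    nbr_cnt = np.zeros(levels.shape, float)
    for off in OFFSETS_26:
        a, b = _shifted_views(levels, off)
        sa, _ = _shifted_views(nbr_sum, off)
        ca, _ = _shifted_views(nbr_cnt, off)
        sa += np.where(b > 0, b, 0)
        ca += (b > 0).astype(float)
    has_nbr = in_roi & (nbr_cnt > 0)
    diff = np.zeros(levels.shape, float)
    diff[has_nbr] = np.abs(
        levels[has_nbr] - nbr_sum[has_nbr] / nbr_cnt[has_nbr]
    )
    n_i = np.bincount(levels[in_roi] - 1, minlength=n_levels).astype(float)
    s_i = np.bincount(levels[has_nbr] - 1, weights=diff[has_nbr], minlength=n_levels)
    return n_i, s_i
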