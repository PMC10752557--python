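"""Texture-matrix construction on discretized 2D grids.

All constructors take ``grid`` (integer levels >= 1, anything outside the
mask is ignored) and ``mask`` (bool, same shape).  Neighborhood
conventions:

* GLCM / GLRLM: the four unique 2D directions at distance 1
  (0deg, 45deg, 90deg, 135deg); pairs/runs count only pixels that are both
  in-mask (out-of-mask pixels break runs, they are never padded).
* GLSZM: 8-connected zones of equal level.
* NGTDM: 3x3 neighborhood (8 neighbors), in-mask neighbors only; in-mask
  pixels with no in-mask neighbor are excluded from the counts.
* GLDM: 4-neighborhood at distance 1, similarity tolerance 0; the stored
  dependence size is (number of dependent neighbors) + 1 so sizes start
  at 1.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# (dr, dc) for 0, 45, 90, 135 degrees
DIRECTIONS_4 = ((0, 1), (1, 1), (1, 0), (1, -1))
GLDM_NEIGHBORS = ((0, 1), (0, -1), (1, 0), (-1, 0))


class MatrixError(ValueError):
    pass


def _check(grid: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    grid = np.asarray(grid)
    mask = np.asarray(mask, bool)
    if grid.shape != mask.shape or grid.ndim != 2:
        raise MatrixError("grid and mask must be congruent 2D arrays")
    if not mask.any():
        raise MatrixError("ROI mask is empty")
    if (grid[mask] < 1).any():
        raise MatrixError("discretized levels must be >= 1 inside the mask")
    return grid.astype(np.int64), mask


def _shifted_pairs(grid, mask, dr, dc):
    """In-mask (center level, neighbor level) pairs for one offset."""
    h, w = grid.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    a = grid[r0:r1, c0:c1]
    b = grid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    return a[valid], b[valid]


def glcm_matrices(grid, mask):
    """Per-direction symmetric co-occurrence count matrices.

    Returns ``(levels, [P_0, P_45, P_90, P_135])`` with P over
    levels x levels; levels are the distinct in-mask values.
    """
    grid, mask = _check(grid, mask)
    levels = np.unique(grid[mask])
    index = {v: i for i, v in enumerate(levels)}
    lut = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    for v, i in index.items():
        lut[v] = i
    mats = []
    for dr, dc in DIRECTIONS_4:
        a, b = _shifted_pairs(grid, mask, dr, dc)
        P = np.zeros((levels.size, levels.size), dtype=np.float64)
        if a.size:
            np.add.at(P, (lut[a], lut[b]), 1.0)
            np.add.at(P, (lut[b], lut[a]), 1.0)  # symmetric
        mats.append(P)
    return levels, mats


def _runs_from_lines(skewed, n_levels, lut):
    """Run-length counts from a 2D array whose ROWS are scan lines.

    Out-of-line / out-of-mask cells must hold 0; levels are >= 1.
    Returns a (n_levels, max_len) count matrix.
    """
    h, w = skewed.shape
    flat = np.concatenate(
        [skewed, np.zeros((h, 1), dtype=skewed.dtype)], axis=1
    ).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [flat.size]))
    lengths = ends - starts
    values = flat[starts]
    keep = values > 0
    values, lengths = values[keep], lengths[keep]
    if values.size == 0:
        return np.zeros((n_levels, 1), dtype=np.float64)
    P = np.zeros((n_levels, int(lengths.max())), dtype=np.float64)
    np.add.at(P, (lut[values], lengths - 1), 1.0)
    return P


def _skew_diagonals(v, anti=False):
    """Rearrange so diagonals (or anti-diagonals) become rows."""
    h, w = v.shape
    out = np.zeros((h + w - 1, max(h, w)), dtype=v.dtype)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    if anti:
        diag = rows + cols
    else:
        diag = cols - rows + (h - 1)
    pos = np.broadcast_to(rows, (h, w))
    out[diag, pos] = v
    return out


def glrlm_matrices(grid, mask):
    """Per-direction run-length count matrices (levels x max run length)."""
    grid, mask = _check(grid, mask)
    levels = np.unique(grid[mask])
    lut = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    for i, v in enumerate(levels):
        lut[v] = i
    v = np.where(mask, grid, 0)
    lines_by_dir = [
        v,                                # 0 deg: rows
        _skew_diagonals(v, anti=True),    # 45 deg: anti-diagonals (dr,dc)=(1,1)? see note
        v.T,                              # 90 deg: columns
        _skew_diagonals(v, anti=False),   # 135 deg
    ]
    mats = []
    max_len = 1
    for lines in lines_by_dir:
        P = _runs_from_lines(lines, levels.size, lut)
        max_len = max(max_len, P.shape[1])
        mats.append(P)
    mats = [
        np.pad(P, ((0, 0), (0, max_len - P.shape[1]))) for P in mats
    ]
    return levels, mats


def glszm_matrix(grid, mask):
    """Size-zone count matrix over 8-connected zones of equal level."""
    grid, mask = _check(grid, mask)
    levels = np.unique(grid[mask])
    structure = np.ones((3, 3), dtype=bool)
    zones = []  # (level index, size)
    for i, lev in enumerate(levels):
        lab, n = ndimage.label((grid == lev) & mask, structure=structure)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((i, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((levels.size, max_size), dtype=np.float64)
    for i, s in zones:
        P[i, s - 1] += 1.0
    return levels, P


def ngtdm_table(grid, mask):
    """Neighboring gray-tone difference table.

    Returns ``(levels, s, p, n_valid)`` where for each distinct in-mask
    level i: ``s[i]`` is the summed absolute difference between the level
    and the mean of its in-mask 3x3 neighbors, and ``p[i]`` the fraction
    of counted pixels carrying that level.
    """
    grid, mask = _check(grid, mask)
    kernel = np.ones((3, 3), dtype=np.float64)
    kernel[1, 1] = 0.0
    m = mask.astype(np.float64)
    nb_sum = ndimage.convolve(grid * m, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    valid = mask & (nb_cnt > 0.5)
    if not valid.any():
        raise MatrixError("no ROI pixel has an in-mask neighbor")
    vals = grid[valid]
    mean_nb = nb_sum[valid] / nb_cnt[valid]
    levels = np.unique(vals)
    lut = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    for i, v in enumerate(levels):
        lut[v] = i
    idx = lut[vals]
    s = np.zeros(levels.size, dtype=np.float64)
    np.add.at(s, idx, np.abs(vals - mean_nb))
    n = np.bincount(idx, minlength=levels.size).astype(np.float64)
    n_valid = int(valid.sum())
    return levels, s, n / n_valid, n_valid


def gldm_matrix(grid, mask):
    """Dependence count matrix (levels x max dependence size).

    Column j (1-based) counts pixels with exactly j-1 equal-level
    4-neighbors inside the mask.
    """
    grid, mask = _check(grid, mask)
    dep = np.zeros(grid.shape, dtype=np.int64)
    for dr, dc in GLDM_NEIGHBORS:
        h, w = grid.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        same = (
            (grid[r0:r1, c0:c1] == grid[r0 + dr:r1 + dr, c0 + dc:c1 + dc])
            & mask[r0:r1, c0:c1]
            & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        )
        dep[r0:r1, c0:c1] += same
    levels = np.unique(grid[mask])
    lut = np.zeros(int(levels.max()) + 1, dtype=np.int64)
    for i, v in enumerate(levels):
        lut[v] = i
    sizes = dep[mask] + 1  # dependence size includes the center pixel
    P = np.zeros((levels.size, int(sizes.max())), dtype=np.float64)
    np.add.at(P, (lut[grid[mask]], sizes - 1), 1.0)
    return levels, P
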