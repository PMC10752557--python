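"""Independent brute-force oracles for the texture-feature families.

Everything here is written as naive per-pixel loops and per-entry formula
sums, sharing no code with the package implementation.  Conventions match
the package contract: distance-1 directions (0/45/90/135 deg), in-mask
pairs only, actual level values in formulas, per-direction feature
averaging for GLCM/GLRLM, 8-connected zones, 3x3 NGTDM neighborhood,
4-neighbor GLDM with dependence size = neighbor count + 1.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

DIRS = [(0, 1), (1, 1), (1, 0), (1, -1)]


def _inside(grid, r, c):
    return 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1]


# ---------------------------------------------------------------- GLCM

def _glcm_counts(grid, mask, dr, dc):
    counts = defaultdict(float)
    h, w = grid.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            r2, c2 = r + dr, c + dc
            if _inside(grid, r2, c2) and mask[r2, c2]:
                a, b = int(grid[r, c]), int(grid[r2, c2])
                counts[(a, b)] += 1
                counts[(b, a)] += 1
    return counts


def _glcm_dir_features(counts):
    total = sum(counts.values())
    p = {k: v / total for k, v in counts.items()}
    levels = sorted({i for i, _ in p} | {j for _, j in p})
    px = {i: sum(p.get((i, j), 0.0) for j in levels) for i in levels}
    levels = [i for i in levels if px[i] > 0]
    px = {i: px[i] for i in levels}
    py = {j: sum(p.get((i, j), 0.0) for i in levels) for j in levels}
    ng = len(levels)
    ux = sum(i * px[i] for i in levels)
    uy = sum(j * py[j] for j in levels)
    sx = math.sqrt(sum(px[i] * (i - ux) ** 2 for i in levels))
    sy = math.sqrt(sum(py[j] * (j - uy) ** 2 for j in levels))

    psum = defaultdict(float)
    pdiff = defaultdict(float)
    for (i, j), v in p.items():
        psum[i + j] += v
        pdiff[abs(i - j)] += v

    f = {}
    f["Autocorrelation"] = sum(v * i * j for (i, j), v in p.items())
    f["ClusterProminence"] = sum(
        v * (i + j - ux - uy) ** 4 for (i, j), v in p.items())
    f["ClusterShade"] = sum(
        v * (i + j - ux - uy) ** 3 for (i, j), v in p.items())
    f["ClusterTendency"] = sum(
        v * (i + j - ux - uy) ** 2 for (i, j), v in p.items())
    f["Contrast"] = sum(v * (i - j) ** 2 for (i, j), v in p.items())
    if sx * sy > 0:
        f["Correlation"] = (f["Autocorrelation"] - ux * uy) / (sx * sy)
    else:
        f["Correlation"] = 1.0
    da = sum(k * v for k, v in pdiff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(
        v * math.log2(v) for v in pdiff.values() if v > 0)
    f["DifferenceVariance"] = sum(
        v * (k - da) ** 2 for k, v in pdiff.items())
    f["Id"] = sum(v / (1 + abs(i - j)) for (i, j), v in p.items())
    f["Idm"] = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
    f["Idmn"] = sum(
        v / (1 + (i - j) ** 2 / ng**2) for (i, j), v in p.items())
    f["Idn"] = sum(v / (1 + abs(i - j) / ng) for (i, j), v in p.items())
    hxy = -sum(v * math.log2(v) for v in p.values() if v > 0)
    hxy1 = -sum(
        v * math.log2(px[i] * py[j]) for (i, j), v in p.items() if v > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in levels for j in levels if px[i] * py[j] > 0)
    hx = -sum(v * math.log2(v) for v in px.values() if v > 0)
    hy = -sum(v * math.log2(v) for v in py.values() if v > 0)
    denom = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    f["Imc2"] = math.sqrt(max(1 - math.exp(-2 * (hxy2 - hxy)), 0.0))
    f["InverseVariance"] = sum(
        v / (i - j) ** 2 for (i, j), v in p.items() if i != j)
    f["JointAverage"] = ux
    f["JointEnergy"] = sum(v * v for v in p.values())
    f["JointEntropy"] = hxy
    if ng > 1:
        Q = np.zeros((ng, ng))
        for a, i in enumerate(levels):
            for b, j in enumerate(levels):
                q = 0.0
                for k in levels:
                    if px[i] > 0 and py[k] > 0:
                        q += p.get((i, k), 0.0) * p.get((j, k), 0.0) / (
                            px[i] * py[k])
                Q[a, b] = q
        eig = sorted(np.linalg.eigvals(Q).real)
        f["MCC"] = math.sqrt(max(eig[-2], 0.0))
    else:
        f["MCC"] = 1.0
    f["MaximumProbability"] = max(p.values())
    f["SumAverage"] = sum(k * v for k, v in psum.items())
    f["SumEntropy"] = -sum(
        v * math.log2(v) for v in psum.values() if v > 0)
    f["SumSquares"] = sum(v * (i - ux) ** 2 for (i, j), v in p.items())
    return f


def oracle_glcm(grid, mask):
    per_dir = []
    for dr, dc in DIRS:
        counts = _glcm_counts(grid, mask, dr, dc)
        if counts:
            per_dir.append(_glcm_dir_features(counts))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ------------------------------------------------- run/zone shared math

def _size_distribution_features(entries, n_pixels, names):
    """entries: dict (level, size) -> count.  names maps generic -> final."""
    nr = sum(entries.values())
    pi = defaultdict(float)
    pj = defaultdict(float)
    for (i, j), v in entries.items():
        pi[i] += v
        pj[j] += v
    mu_i = sum(i * v for i, v in pi.items()) / nr
    mu_j = sum(j * v for j, v in pj.items()) / nr
    f = {}
    f["Short"] = sum(v / j**2 for (i, j), v in entries.items()) / nr
    f["Long"] = sum(v * j**2 for (i, j), v in entries.items()) / nr
    f["GrayLevelNonUniformity"] = sum(v**2 for v in pi.values()) / nr
    f["GrayLevelNonUniformityNormalized"] = sum(
        v**2 for v in pi.values()) / nr**2
    f["SizeNonUniformity"] = sum(v**2 for v in pj.values()) / nr
    f["SizeNonUniformityNormalized"] = sum(
        v**2 for v in pj.values()) / nr**2
    f["Percentage"] = nr / n_pixels
    f["GrayLevelVariance"] = sum(
        (v / nr) * (i - mu_i) ** 2 for (i, j), v in entries.items())
    f["SizeVariance"] = sum(
        (v / nr) * (j - mu_j) ** 2 for (i, j), v in entries.items())
    f["Entropy"] = -sum(
        (v / nr) * math.log2(v / nr) for v in entries.values() if v > 0)
    f["LowGrayLevel"] = sum(v / i**2 for (i, j), v in entries.items()) / nr
    f["HighGrayLevel"] = sum(v * i**2 for (i, j), v in entries.items()) / nr
    f["ShortLow"] = sum(
        v / (i**2 * j**2) for (i, j), v in entries.items()) / nr
    f["ShortHigh"] = sum(
        v * i**2 / j**2 for (i, j), v in entries.items()) / nr
    f["LongLow"] = sum(
        v * j**2 / i**2 for (i, j), v in entries.items()) / nr
    f["LongHigh"] = sum(
        v * i**2 * j**2 for (i, j), v in entries.items()) / nr
    return {names[k]: v for k, v in f.items()}


_RUN_NAMES = {
    "Short": "ShortRunEmphasis", "Long": "LongRunEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "RunLengthNonUniformity",
    "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
    "Percentage": "RunPercentage", "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "RunVariance", "Entropy": "RunEntropy",
    "LowGrayLevel": "LowGrayLevelRunEmphasis",
    "HighGrayLevel": "HighGrayLevelRunEmphasis",
    "ShortLow": "ShortRunLowGrayLevelEmphasis",
    "ShortHigh": "ShortRunHighGrayLevelEmphasis",
    "LongLow": "LongRunLowGrayLevelEmphasis",
    "LongHigh": "LongRunHighGrayLevelEmphasis",
}

_ZONE_NAMES = {
    "Short": "SmallAreaEmphasis", "Long": "LargeAreaEmphasis",
    "GrayLevelNonUniformity": "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
    "SizeNonUniformity": "SizeZoneNonUniformity",
    "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
    "Percentage": "ZonePercentage", "GrayLevelVariance": "GrayLevelVariance",
    "SizeVariance": "ZoneVariance", "Entropy": "ZoneEntropy",
    "LowGrayLevel": "LowGrayLevelZoneEmphasis",
    "HighGrayLevel": "HighGrayLevelZoneEmphasis",
    "ShortLow": "SmallAreaLowGrayLevelEmphasis",
    "ShortHigh": "SmallAreaHighGrayLevelEmphasis",
    "LongLow": "LargeAreaLowGrayLevelEmphasis",
    "LongHigh": "LargeAreaHighGrayLevelEmphasis",
}


def oracle_run_inventory(grid, mask, dr, dc):
    """All (level, run length) runs in one direction, via start-and-walk."""
    runs = defaultdict(float)
    h, w = grid.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            if (_inside(grid, pr, pc) and mask[pr, pc]
                    and grid[pr, pc] == grid[r, c]):
                continue  # not a run start
            length = 1
            nr_, nc_ = r + dr, c + dc
            while (_inside(grid, nr_, nc_) and mask[nr_, nc_]
                   and grid[nr_, nc_] == grid[r, c]):
                length += 1
                nr_, nc_ = nr_ + dr, nc_ + dc
            runs[(int(grid[r, c]), length)] += 1
    return runs


def oracle_glrlm(grid, mask):
    n_pixels = int(mask.sum())
    per_dir = []
    for dr, dc in DIRS:
        runs = oracle_run_inventory(grid, mask, dr, dc)
        per_dir.append(
            _size_distribution_features(runs, n_pixels, _RUN_NAMES))
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def oracle_zone_inventory(grid, mask):
    """8-connected equal-level zones via explicit flood fill."""
    h, w = grid.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = defaultdict(float)
    for r in range(h):
        for c in range(w):
            if not mask[r, c] or seen[r, c]:
                continue
            level = int(grid[r, c])
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (_inside(grid, r2, c2) and mask[r2, c2]
                                and not seen[r2, c2]
                                and int(grid[r2, c2]) == level):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones[(level, size)] += 1
    return zones


def oracle_glszm(grid, mask):
    zones = oracle_zone_inventory(grid, mask)
    return _size_distribution_features(zones, int(mask.sum()), _ZONE_NAMES)


def oracle_ngtdm(grid, mask):
    h, w = grid.shape
    s = defaultdict(float)
    n = defaultdict(int)
    n_valid = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if _inside(grid, r2, c2) and mask[r2, c2]:
                        nb.append(float(grid[r2, c2]))
            if not nb:
                continue
            n_valid += 1
            lev = int(grid[r, c])
            n[lev] += 1
            s[lev] += abs(lev - sum(nb) / len(nb))
    levels = sorted(n)
    p = {i: n[i] / n_valid for i in levels}
    ngp = len(levels)
    ps = sum(p[i] * s[i] for i in levels)
    ssum = sum(s.values())
    f = {}
    f["Coarseness"] = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        f["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
            / (ngp * (ngp - 1)) * ssum / n_valid
        )
        bden = sum(
            abs(i * p[i] - j * p[j]) for i in levels for j in levels)
        f["Busyness"] = ps / bden if bden > 0 else 0.0
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
    f["Complexity"] = sum(
        abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
        for i in levels for j in levels) / n_valid
    f["Strength"] = (
        sum((p[i] + p[j]) * (i - j) ** 2 for i in levels for j in levels)
        / ssum if ssum > 0 else 0.0
    )
    return f


def oracle_gldm(grid, mask):
    h, w = grid.shape
    entries = defaultdict(float)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if (_inside(grid, r2, c2) and mask[r2, c2]
                        and grid[r2, c2] == grid[r, c]):
                    dep += 1
            entries[(int(grid[r, c]), dep + 1)] += 1
    nz = sum(entries.values())
    pi = defaultdict(float)
    pj = defaultdict(float)
    for (i, j), v in entries.items():
        pi[i] += v
        pj[j] += v
    mu_i = sum(i * v for i, v in pi.items()) / nz
    mu_j = sum(j * v for j, v in pj.items()) / nz
    return {
        "SmallDependenceEmphasis": sum(
            v / j**2 for (i, j), v in entries.items()) / nz,
        "LargeDependenceEmphasis": sum(
            v * j**2 for (i, j), v in entries.items()) / nz,
        "GrayLevelNonUniformity": sum(v**2 for v in pi.values()) / nz,
        "DependenceNonUniformity": sum(v**2 for v in pj.values()) / nz,
        "DependenceNonUniformityNormalized": sum(
            v**2 for v in pj.values()) / nz**2,
        "GrayLevelVariance": sum(
            (v / nz) * (i - mu_i) ** 2 for (i, j), v in entries.items()),
        "DependenceVariance": sum(
            (v / nz) * (j - mu_j) ** 2 for (i, j), v in entries.items()),
        "DependenceEntropy": -sum(
            (v / nz) * math.log2(v / nz) for v in entries.values() if v > 0),
        "LowGrayLevelEmphasis": sum(
            v / i**2 for (i, j), v in entries.items()) / nz,
        "HighGrayLevelEmphasis": sum(
            v * i**2 for (i, j), v in entries.items()) / nz,
        "SmallDependenceLowGrayLevelEmphasis": sum(
            v / (i**2 * j**2) for (i, j), v in entries.items()) / nz,
        "SmallDependenceHighGrayLevelEmphasis": sum(
            v * i**2 / j**2 for (i, j), v in entries.items()) / nz,
        "LargeDependenceLowGrayLevelEmphasis": sum(
            v * j**2 / i**2 for (i, j), v in entries.items()) / nz,
        "LargeDependenceHighGrayLevelEmphasis": sum(
            v * i**2 * j**2 for (i, j), v in entries.items()) / nz,
    }


def random_grid(seed, max_side=8, max_levels=6):
    """Random discretized grid + mask (mask guaranteed >= 4 connected-ish px)."""
    rng = np.random.default_rng(seed)
    h = int(rng.integers(2, max_side + 1))
    w = int(rng.integers(2, max_side + 1))
    levels = int(rng.integers(1, max_levels + 1))
    grid = rng.integers(1, levels + 1, size=(h, w))
    mask = rng.random((h, w)) < 0.8
    # ensure a 2x2 in-mask block so every family has work to do
    r0 = int(rng.integers(0, h - 1))
    c0 = int(rng.integers(0, w - 1))
    mask[r0:r0 + 2, c0:c0 + 2] = True
    return grid.astype(np.int64), mask
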