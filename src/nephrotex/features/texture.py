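"""Feature formulas for the five texture-matrix families.

Formulas weight by the actual discretized level values (not matrix row
indices); distribution entropies use log base 2 over nonzero
probabilities.  Degenerate rules (single gray level, empty denominators)
are fixed and reported through the optional ``flags`` dict:

* GLCM correlation and MCC are 1 for a single-level ROI;
* NGTDM coarseness is capped at 1e6 when sum(p*s) == 0;
* NGTDM contrast/busyness/strength are 0 when undefined.
"""

from __future__ import annotations

import numpy as np

from .matrices import (glcm_matrices, gldm_matrix, glrlm_matrices,
                       glszm_matrix, ngtdm_table)

COARSENESS_CAP = 1e6


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _glcm_single(P: np.ndarray, levels: np.ndarray, flags) -> dict[str, float]:
    total = P.sum()
    p = P / total
    # drop levels absent from this direction's pairs
    keep = p.sum(axis=1) > 0
    p = p[np.ix_(keep, keep)]
    iv = levels[keep].astype(np.float64)
    ng = iv.size
    I, J = np.meshgrid(iv, iv, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float((iv * px).sum())
    uy = float((iv * py).sum())
    sx = float(np.sqrt((((iv - ux) ** 2) * px).sum()))
    sy = float(np.sqrt((((iv - uy) ** 2) * py).sum()))

    sum_vals = (I + J).astype(np.int64)
    diff_vals = np.abs(I - J).astype(np.int64)
    psum = np.bincount(sum_vals.ravel(), weights=p.ravel())
    pdiff = np.bincount(diff_vals.ravel(), weights=p.ravel())
    ks = np.arange(psum.size, dtype=np.float64)
    kd = np.arange(pdiff.size, dtype=np.float64)

    out: dict[str, float] = {}
    out["Autocorrelation"] = float((p * I * J).sum())
    ct = I + J - ux - uy
    out["ClusterProminence"] = float((p * ct**4).sum())
    out["ClusterShade"] = float((p * ct**3).sum())
    out["ClusterTendency"] = float((p * ct**2).sum())
    out["Contrast"] = float((p * (I - J) ** 2).sum())
    if sx * sy > 0:
        out["Correlation"] = float(
            ((p * I * J).sum() - ux * uy) / (sx * sy)
        )
    else:
        out["Correlation"] = 1.0
        flags.setdefault("glcm_Correlation", "single gray level; set to 1")
    da = float((kd * pdiff).sum())
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = _entropy2(pdiff)
    out["DifferenceVariance"] = float((((kd - da) ** 2) * pdiff).sum())
    absdiff = np.abs(I - J)
    out["Id"] = float((p / (1.0 + absdiff)).sum())
    out["Idm"] = float((p / (1.0 + absdiff**2)).sum())
    out["Idmn"] = float((p / (1.0 + absdiff**2 / ng**2)).sum())
    out["Idn"] = float((p / (1.0 + absdiff / ng)).sum())

    hxy = _entropy2(p.ravel())
    pxy = np.outer(px, py)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    hxy2 = _entropy2(pxy.ravel())
    hx, hy = _entropy2(px), _entropy2(py)
    denom = max(hx, hy)
    out["Imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["Imc2"] = float(np.sqrt(max(arg, 0.0)))
    offdiag = absdiff > 0
    out["InverseVariance"] = float(
        (p[offdiag] / (absdiff[offdiag] ** 2)).sum()
    )
    out["JointAverage"] = ux
    out["JointEnergy"] = float((p**2).sum())
    out["JointEntropy"] = hxy
    if ng > 1:
        A = p / px[:, None]
        B = p / py[None, :]
        Q = A @ B.T
        eig = np.sort(np.linalg.eigvals(Q).real)
        out["MCC"] = float(np.sqrt(max(eig[-2], 0.0)))
    else:
        out["MCC"] = 1.0
        flags.setdefault("glcm_MCC", "single gray level; set to 1")
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = float((ks * psum).sum())
    out["SumEntropy"] = _entropy2(psum)
    out["SumSquares"] = float((p * (I - ux) ** 2).sum())
    return out


def glcm_features(grid, mask, flags=None) -> dict[str, float]:
    """24 co-occurrence features, per-direction values averaged."""
    flags = flags if flags is not None else {}
    levels, mats = glcm_matrices(grid, mask)
    per_dir = [
        _glcm_single(P, levels, flags) for P in mats if P.sum() > 0
    ]
    if not per_dir:
        raise ValueError("no valid pixel pairs in any direction")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def _rl_single(P: np.ndarray, levels: np.ndarray, n_pixels: int,
               kind: str) -> dict[str, float]:
    """Shared run-length / size-zone formulas; kind in {'run', 'zone'}."""
    nr = P.sum()
    iv = levels.astype(np.float64)
    jv = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    i2 = iv**2
    j2 = jv**2
    pi = P.sum(axis=1)  # per gray level
    pj = P.sum(axis=0)  # per length/size
    p = P / nr
    mu_i = float((iv * pi / nr).sum())
    mu_j = float((jv * pj / nr).sum())

    short = float((P / j2[None, :]).sum() / nr)
    long_ = float((P * j2[None, :]).sum() / nr)
    out = {
        "GrayLevelNonUniformity": float((pi**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pi**2).sum() / nr**2),
        "GrayLevelVariance": float((p * ((iv - mu_i)[:, None] ** 2)).sum()),
        "LowGrayLevel": float((P / i2[:, None]).sum() / nr),
        "HighGrayLevel": float((P * i2[:, None]).sum() / nr),
        "ShortLow": float((P / np.outer(i2, j2)).sum() / nr),
        "ShortHigh": float((P * i2[:, None] / j2[None, :]).sum() / nr),
        "LongLow": float((P * j2[None, :] / i2[:, None]).sum() / nr),
        "LongHigh": float((P * np.outer(i2, j2)).sum() / nr),
        "SizeVariance": float((p * ((jv - mu_j)[None, :] ** 2)).sum()),
        "Entropy": _entropy2(p.ravel()),
        "Percentage": float(nr / n_pixels),
        "SizeNonUniformity": float((pj**2).sum() / nr),
        "SizeNonUniformityNormalized": float((pj**2).sum() / nr**2),
        "Short": short,
        "Long": long_,
    }
    return out


_RL_RENAME = {
    "run": {
        "Short": "ShortRunEmphasis", "Long": "LongRunEmphasis",
        "SizeNonUniformity": "RunLengthNonUniformity",
        "SizeNonUniformityNormalized": "RunLengthNonUniformityNormalized",
        "Percentage": "RunPercentage", "SizeVariance": "RunVariance",
        "Entropy": "RunEntropy",
        "LowGrayLevel": "LowGrayLevelRunEmphasis",
        "HighGrayLevel": "HighGrayLevelRunEmphasis",
        "ShortLow": "ShortRunLowGrayLevelEmphasis",
        "ShortHigh": "ShortRunHighGrayLevelEmphasis",
        "LongLow": "LongRunLowGrayLevelEmphasis",
        "LongHigh": "LongRunHighGrayLevelEmphasis",
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance": "GrayLevelVariance",
    },
    "zone": {
        "Short": "SmallAreaEmphasis", "Long": "LargeAreaEmphasis",
        "SizeNonUniformity": "SizeZoneNonUniformity",
        "SizeNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "Percentage": "ZonePercentage", "SizeVariance": "ZoneVariance",
        "Entropy": "ZoneEntropy",
        "LowGrayLevel": "LowGrayLevelZoneEmphasis",
        "HighGrayLevel": "HighGrayLevelZoneEmphasis",
        "ShortLow": "SmallAreaLowGrayLevelEmphasis",
        "ShortHigh": "SmallAreaHighGrayLevelEmphasis",
        "LongLow": "LargeAreaLowGrayLevelEmphasis",
        "LongHigh": "LargeAreaHighGrayLevelEmphasis",
        "GrayLevelNonUniformity": "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized": "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance": "GrayLevelVariance",
    },
}


def glrlm_features(grid, mask, flags=None) -> dict[str, float]:
    """16 run-length features, per-direction values averaged."""
    levels, mats = glrlm_matrices(grid, mask)
    n_pixels = int(np.asarray(mask, bool).sum())
    rename = _RL_RENAME["run"]
    per_dir = [_rl_single(P, levels, n_pixels, "run") for P in mats]
    return {
        rename[k]: float(np.mean([d[k] for d in per_dir]))
        for k in per_dir[0]
    }


def glszm_features(grid, mask, flags=None) -> dict[str, float]:
    """16 size-zone features from the single 8-connectivity zone matrix."""
    levels, P = glszm_matrix(grid, mask)
    n_pixels = int(np.asarray(mask, bool).sum())
    rename = _RL_RENAME["zone"]
    raw = _rl_single(P, levels, n_pixels, "zone")
    return {rename[k]: v for k, v in raw.items()}


def ngtdm_features(grid, mask, flags=None) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    flags = flags if flags is not None else {}
    levels, s, p, n_valid = ngtdm_table(grid, mask)
    iv = levels.astype(np.float64)
    ngp = int((p > 0).sum())
    ps = float((p * s).sum())

    out: dict[str, float] = {}
    if ps > 0:
        out["Coarseness"] = float(1.0 / ps)
    else:
        out["Coarseness"] = COARSENESS_CAP
        flags.setdefault("ngtdm_Coarseness",
                         f"sum(p*s)=0; capped at {COARSENESS_CAP:g}")
    I, J = np.meshgrid(iv, iv, indexing="ij")
    PiPj = np.outer(p, p)
    if ngp > 1:
        out["Contrast"] = float(
            (PiPj * (I - J) ** 2).sum() / (ngp * (ngp - 1)) * s.sum() / n_valid
        )
        busy_den = float(np.abs(I * p[:, None] - J * p[None, :]).sum())
        out["Busyness"] = float(ps / busy_den) if busy_den > 0 else 0.0
    else:
        out["Contrast"] = 0.0
        out["Busyness"] = 0.0
        flags.setdefault("ngtdm_Contrast", "single gray level; set to 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_si = p * s
        num = np.abs(I - J) * (pi_si[:, None] + pi_si[None, :])
        den = p[:, None] + p[None, :]
        term = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out["Complexity"] = float(term.sum() / n_valid)
    ssum = float(s.sum())
    if ssum > 0:
        out["Strength"] = float(
            ((p[:, None] + p[None, :]) * (I - J) ** 2).sum() / ssum
        )
    else:
        out["Strength"] = 0.0
        flags.setdefault("ngtdm_Strength", "sum(s)=0; set to 0")
    return out


def gldm_features(grid, mask, flags=None) -> dict[str, float]:
    """14 dependence-matrix features."""
    levels, P = gldm_matrix(grid, mask)
    nz = P.sum()
    iv = levels.astype(np.float64)
    jv = np.arange(1, P.shape[1] + 1, dtype=np.float64)
    i2, j2 = iv**2, jv**2
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    p = P / nz
    mu_i = float((iv * pi / nz).sum())
    mu_j = float((jv * pj / nz).sum())
    return {
        "SmallDependenceEmphasis": float((P / j2[None, :]).sum() / nz),
        "LargeDependenceEmphasis": float((P * j2[None, :]).sum() / nz),
        "GrayLevelNonUniformity": float((pi**2).sum() / nz),
        "DependenceNonUniformity": float((pj**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj**2).sum() / nz**2),
        "GrayLevelVariance": float((p * ((iv - mu_i)[:, None] ** 2)).sum()),
        "DependenceVariance": float((p * ((jv - mu_j)[None, :] ** 2)).sum()),
        "DependenceEntropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float((P / i2[:, None]).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i2[:, None]).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(
            (P / np.outer(i2, j2)).sum() / nz
        ),
        "SmallDependenceHighGrayLevelEmphasis": float(
            (P * i2[:, None] / j2[None, :]).sum() / nz
        ),
        "LargeDependenceLowGrayLevelEmphasis": float(
            (P * j2[None, :] / i2[:, None]).sum() / nz
        ),
        "LargeDependenceHighGrayLevelEmphasis": float(
            (P * np.outer(i2, j2)).sum() / nz
        ),
    }
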