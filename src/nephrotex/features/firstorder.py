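"""First-order intensity statistics (18 features).

All features are computed on the raw (normalized) ROI intensities except
entropy and uniformity, which use the discretized histogram — the same
split the canonical reference implementation makes.  Variance, skewness
and kurtosis use population (1/N) moments; kurtosis is NOT excess
kurtosis (a normal distribution scores 3).
"""

from __future__ import annotations

import numpy as np


def first_order_features(raw_values: np.ndarray,
                         discretized_values: np.ndarray,
                         pixel_area_mm2: float = 1.0,
                         flags: dict | None = None) -> dict[str, float]:
    flags = flags if flags is not None else {}
    x = np.asarray(raw_values, dtype=np.float64).ravel()
    d = np.asarray(discretized_values, dtype=np.int64).ravel()
    if x.size == 0:
        raise ValueError("ROI is empty")
    if x.size != d.size:
        raise ValueError("raw and discretized ROIs differ in size")

    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    hist = np.bincount(d)[1:].astype(np.float64)
    p = hist[hist > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if m2 > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = 0.0
        kurt = 0.0
        flags.setdefault("firstorder_Skewness", "zero variance; set to 0")
        flags.setdefault("firstorder_Kurtosis", "zero variance; set to 0")
    if n == 1:
        flags.setdefault("firstorder_Skewness", "single-pixel ROI")
        flags.setdefault("firstorder_Kurtosis", "single-pixel ROI")

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": float(pixel_area_mm2 * energy),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": m2,
        "Uniformity": uniformity,
    }
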