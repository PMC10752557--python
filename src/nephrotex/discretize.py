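"""Fixed-bin-size (FBS) gray-level discretization.

The bin width W is derived from the cohort, not the single image:
``W = mean(per-image whole-image intensity range) / N_b``, so a given
bin count means the same physical bin width across every image of an arm.
Discretization then maps ROI intensities to positive integer levels

    X_fbs = floor(X / W) - floor(min(X_roi) / W) + 1

which anchors the minimum discretized level at 1 for every ROI (the
pyradiomics FBS dialect: the anchor uses the ROI minimum, not a fixed
origin as in IBSI).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np


class DiscretizationError(ValueError):
    pass


@dataclass(frozen=True)
class DiscretizationScheme:
    """Cohort-level FBS scheme: N_b bins of width W = range_mean / N_b."""

    n_bins: int
    range_mean: float
    bin_width: float

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise DiscretizationError("n_bins must be >= 2")
        if self.bin_width <= 0:
            raise DiscretizationError("bin_width must be positive")


@dataclass
class DiscretizedROI:
    """Positive integer bin indices per ROI pixel; min(values) == 1."""

    values: np.ndarray
    n_levels_observed: int
    scheme: DiscretizationScheme


def cohort_bin_width(cohort_images: Iterable[np.ndarray],
                     n_bins: int) -> DiscretizationScheme:
    """Cohort-derived FBS scheme from whole-image intensity ranges."""
    ranges = []
    for img in cohort_images:
        img = np.asarray(img, dtype=np.float64)
        if img.size == 0:
            raise DiscretizationError("empty image in cohort")
        r = float(img.max() - img.min())
        if r == 0:
            raise DiscretizationError(
                "constant image in cohort: gray-level range is zero"
            )
        ranges.append(r)
    if not ranges:
        raise DiscretizationError("cohort must contain at least one image")
    if n_bins < 2:
        raise DiscretizationError("n_bins must be >= 2")
    range_mean = float(np.mean(ranges))
    return DiscretizationScheme(n_bins=int(n_bins), range_mean=range_mean,
                                bin_width=range_mean / n_bins)


def fbs_discretize(roi_values: np.ndarray,
                   scheme: DiscretizationScheme) -> DiscretizedROI:
    """Discretize ROI intensities; output levels are integers starting at 1."""
    roi_values = np.asarray(roi_values, dtype=np.float64)
    if roi_values.size == 0:
        raise DiscretizationError("ROI is empty")
    w = scheme.bin_width
    if w <= 0:
        raise DiscretizationError("bin width must be positive")
    binned = np.floor(roi_values / w)
    levels = (binned - np.floor(roi_values.min() / w) + 1).astype(np.int64)
    return DiscretizedROI(
        values=levels,
        n_levels_observed=int(np.unique(levels).size),
        scheme=scheme,
    )
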