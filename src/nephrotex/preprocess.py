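"""Intensity normalization, matrix resizing, and pixel resampling.

Three normalization arms are studied:

* ``original`` — no normalization,
* ``zscore``   — (X - mu) / sigma with mu, sigma over the ENTIRE image
  (background included),
* ``reference`` — affine map driving a reference-tissue ROI (psoas muscle)
  to mean 100 and standard deviation 10.

Both normalizations are affine, so any affine-invariant first-order
statistic (skewness, kurtosis, correlation) is untouched by arm choice —
the mechanism behind reproducible features in this design.

Spatial harmonization uses nearest-neighbor interpolation with a fixed
pixel-center convention (ties toward the lower index) so results are
bit-exact and testable.  Pipeline order is fixed: normalize on the native
image, resize to the analysis matrix, then resample to the target spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NORMALIZATIONS = ("original", "zscore", "reference")
RESAMPLINGS = ("up_1.0mm", "down_2.0mm")
RESAMPLING_SPACING = {"up_1.0mm": 1.0, "down_2.0mm": 2.0}
GRAY_LEVELS = (8, 16, 32, 64, 128, 256)
ANALYSIS_MATRIX = 256

REFERENCE_TARGET_MEAN = 100.0
REFERENCE_TARGET_SD = 10.0


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationStats:
    """Mean/SD used by a normalization arm, and where they came from."""

    mu: float
    sigma: float
    region: str  # "entire_image" or "reference_roi"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise PreprocessError("sigma must be >= 0")

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0


@dataclass(frozen=True, order=True)
class PreprocessSetting:
    """One cell of the preprocessing grid: (normalization, resampling, bins)."""

    normalization: str
    resampling: str
    n_gray_levels: int

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise PreprocessError(f"unknown normalization {self.normalization!r}")
        if self.resampling not in RESAMPLINGS:
            raise PreprocessError(f"unknown resampling {self.resampling!r}")
        if self.n_gray_levels < 2:
            raise PreprocessError("n_gray_levels must be >= 2")

    @property
    def tag(self) -> str:
        return f"{self.normalization}_{self.resampling}_Nb{self.n_gray_levels}"


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Whole-image z-score: X' = (X - mu) / sigma, moments over ALL pixels."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise PreprocessError("empty image")
    mu = image.mean()
    sigma = image.std()
    if sigma == 0:
        raise PreprocessError("degenerate normalization: whole-image SD is zero")
    return (image - mu) / sigma


def reference_normalize(image: np.ndarray, reference_mask: np.ndarray) -> np.ndarray:
    """Map the whole image so the reference ROI has mean 100 and SD 10."""
    image = np.asarray(image, dtype=np.float64)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != image.shape:
        raise PreprocessError("reference mask shape differs from image")
    if not reference_mask.any():
        raise PreprocessError("reference mask is empty")
    vals = image[reference_mask]
    mu, sigma = vals.mean(), vals.std()
    if sigma == 0:
        raise PreprocessError("degenerate normalization: reference ROI SD is zero")
    return REFERENCE_TARGET_SD * (image - mu) / sigma + REFERENCE_TARGET_MEAN


def normalization_stats(image: np.ndarray, normalization: str,
                        reference_mask: np.ndarray | None = None) -> NormalizationStats:
    image = np.asarray(image, dtype=np.float64)
    if normalization == "zscore":
        return NormalizationStats(float(image.mean()), float(image.std()),
                                  "entire_image")
    if normalization == "reference":
        if reference_mask is None or not np.asarray(reference_mask, bool).any():
            raise PreprocessError("reference normalization needs a nonempty mask")
        vals = image[np.asarray(reference_mask, bool)]
        return NormalizationStats(float(vals.mean()), float(vals.std()),
                                  "reference_roi")
    if normalization == "original":
        return NormalizationStats(0.0, 1.0, "entire_image")
    raise PreprocessError(f"unknown normalization {normalization!r}")


def _nn_indices(n_out: int, n_in: int) -> np.ndarray:
    # output pixel center mapped into input pixel coordinates; nearest
    # neighbor with ties broken toward the lower index via ceil(x - 0.5)
    centers = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    idx = np.ceil(centers - 0.5).astype(int)
    return np.clip(idx, 0, n_in - 1)


def resize_to_matrix(arr: np.ndarray, target_px: int,
                     is_mask: bool = False) -> np.ndarray:
    """Nearest-neighbor resize of a square grid to target_px x target_px."""
    if target_px <= 0:
        raise PreprocessError("target_px must be positive")
    arr = np.asarray(arr)
    if arr.shape[0] == target_px and arr.shape[1] == target_px:
        return arr.copy()
    ri = _nn_indices(target_px, arr.shape[0])
    ci = _nn_indices(target_px, arr.shape[1])
    out = arr[np.ix_(ri, ci)]
    return out.astype(bool) if is_mask else out


def resample_to_spacing(arr: np.ndarray, source_spacing: float,
                        target_spacing: float,
                        is_mask: bool = False) -> tuple[np.ndarray, float]:
    """Nearest-neighbor resample to a new pixel spacing (mm).

    Output grid size is round(extent / target spacing) per axis.
    Returns (resampled array, target spacing).
    """
    if source_spacing is None or source_spacing <= 0:
        raise PreprocessError("source pixel spacing missing or non-positive")
    if target_spacing <= 0:
        raise PreprocessError("target spacing must be positive")
    arr = np.asarray(arr)
    if source_spacing == target_spacing:
        return arr.copy(), float(target_spacing)
    out_shape = [
        max(1, int(np.round(n * source_spacing / target_spacing)))
        for n in arr.shape[:2]
    ]
    ri = _nn_indices(out_shape[0], arr.shape[0])
    ci = _nn_indices(out_shape[1], arr.shape[1])
    out = arr[np.ix_(ri, ci)]
    return (out.astype(bool) if is_mask else out), float(target_spacing)


def noncystic_mask(kidney_mask: np.ndarray, cyst_mask: np.ndarray) -> np.ndarray:
    """Kidney minus cysts: the noncystic parenchyma ROI."""
    kidney_mask = np.asarray(kidney_mask, bool)
    cyst_mask = np.asarray(cyst_mask, bool)
    if kidney_mask.shape != cyst_mask.shape:
        raise PreprocessError("kidney and cyst masks are not congruent")
    out = kidney_mask & ~cyst_mask
    if not out.any():
        raise PreprocessError("noncystic ROI is empty (cysts cover the kidney)")
    return out


def preprocess_case(case, setting: PreprocessSetting,
                    analysis_matrix: int = ANALYSIS_MATRIX):
    """Apply one grid cell's normalization + resize + resample to a case.

    Returns ``(image, masks, spacing)`` where ``masks`` is a dict with
    kidney / cyst / psoas entries on the output grid.  Normalization
    statistics are always taken on the native-resolution image (reference
    stats from the native psoas mask) so they are interpolation-free.
    """
    if setting.normalization == "zscore":
        img = zscore_normalize(case.image)
    elif setting.normalization == "reference":
        img = reference_normalize(case.image, case.psoas_mask)
    else:
        img = np.asarray(case.image, dtype=np.float64).copy()

    native = case.image.shape[0]
    img = resize_to_matrix(img, analysis_matrix)
    spacing = case.pixel_spacing * native / analysis_matrix
    masks = {
        "kidney": resize_to_matrix(case.kidney_mask, analysis_matrix, is_mask=True),
        "cyst": resize_to_matrix(case.cyst_mask, analysis_matrix, is_mask=True),
        "psoas": resize_to_matrix(case.psoas_mask, analysis_matrix, is_mask=True),
    }
    target = RESAMPLING_SPACING[setting.resampling]
    img, out_spacing = resample_to_spacing(img, spacing, target)
    for name in masks:
        masks[name], _ = resample_to_spacing(masks[name], spacing, target,
                                             is_mask=True)
    return img, masks, out_spacing
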