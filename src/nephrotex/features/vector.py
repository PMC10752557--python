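"""Assembly of the 93-feature vector for one ROI of one case."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..discretize import DiscretizationScheme, fbs_discretize
from ..preprocess import PreprocessSetting, noncystic_mask, preprocess_case
from .firstorder import first_order_features
from .names import FEATURE_NAMES
from .texture import (glcm_features, gldm_features, glrlm_features,
                      glszm_features, ngtdm_features)

ROI_KINDS = ("noncystic", "entire_kidney")


@dataclass
class FeatureVector:
    """93 named feature values plus provenance and degeneracy flags."""

    values: dict[str, float]
    case_id: str
    roi_kind: str
    setting: PreprocessSetting
    flags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            raise ValueError(
                f"feature vector must carry exactly the 93 canonical names "
                f"in order (missing: {sorted(missing)[:5]}...)"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.case_id)


def extract_from_preprocessed(image: np.ndarray, roi_mask: np.ndarray,
                              spacing_mm: float, scheme: DiscretizationScheme,
                              case_id: str = "", roi_kind: str = "noncystic",
                              setting: PreprocessSetting | None = None
                              ) -> FeatureVector:
    """Extract the 93-feature panel from an already-preprocessed image."""
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    raw = np.asarray(image, np.float64)[roi_mask]
    disc = fbs_discretize(raw, scheme)
    grid = np.zeros(roi_mask.shape, dtype=np.int64)
    grid[roi_mask] = disc.values

    flags: dict[str, str] = {}
    fams = {
        "firstorder": first_order_features(raw, disc.values,
                                           pixel_area_mm2=spacing_mm**2,
                                           flags=flags),
        "glcm": glcm_features(grid, roi_mask, flags=flags),
        "glrlm": glrlm_features(grid, roi_mask, flags=flags),
        "glszm": glszm_features(grid, roi_mask, flags=flags),
        "ngtdm": ngtdm_features(grid, roi_mask, flags=flags),
        "gldm": gldm_features(grid, roi_mask, flags=flags),
    }
    flat = {f"{fam}_{k}": v for fam, d in fams.items() for k, v in d.items()}
    values = {name: flat[name] for name in FEATURE_NAMES}
    if setting is None:
        setting = PreprocessSetting("original", "up_1.0mm", scheme.n_bins)
    return FeatureVector(values=values, case_id=case_id, roi_kind=roi_kind,
                         setting=setting, flags=flags)


def extract_feature_vector(case, roi_kind: str, setting: PreprocessSetting,
                           scheme: DiscretizationScheme) -> FeatureVector:
    """Preprocess a phantom case under one grid cell and extract features."""
    if roi_kind not in ROI_KINDS:
        raise ValueError(f"roi_kind must be one of {ROI_KINDS}")
    image, masks, spacing = preprocess_case(case, setting)
    if roi_kind == "noncystic":
        roi = noncystic_mask(masks["kidney"], masks["cyst"])
    else:
        roi = masks["kidney"]
    return extract_from_preprocessed(
        image, roi, spacing, scheme,
        case_id=case.case_id or f"seed{case.seed}",
        roi_kind=roi_kind, setting=setting,
    )


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Feature table: one row per vector, provenance + 93 feature columns."""
    rows = []
    for v in vectors:
        row = {
            "case_id": v.case_id,
            "roi_kind": v.roi_kind,
            "normalization": v.setting.normalization,
            "resampling": v.setting.resampling,
            "n_gray_levels": v.setting.n_gray_levels,
            "n_flags": len(v.flags),
        }
        row.update(v.values)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(rows[0].keys()) if rows else None)
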