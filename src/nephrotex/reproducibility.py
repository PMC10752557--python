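"""Feature reproducibility across normalization arms via ICC(3,1).

The intraclass correlation uses the two-way mixed-effects, consistency,
single-rater model: rows are observation units (kidneys), columns are
"raters" (the normalization arms).  From the two-way ANOVA decomposition

    ICC = (MSR - MSE) / (MSR + (k - 1) * MSE)

where MSR is the mean square for rows and MSE the residual mean square.
Consistency ICC ignores fixed rater offsets (a column shift leaves it at
1) and can be negative; negative values are reported as computed and
categorized as poor.

Categories: icc < 0.5 poor; 0.5 <= icc < 0.75 moderate;
icc >= 0.75 good-to-excellent (good and excellent bands merged).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features.names import FAMILY_NAMES, FEATURE_NAMES

CATEGORIES = ("poor", "moderate", "good_to_excellent")
DEFAULT_RATERS = ("original", "zscore", "reference")


class ReproducibilityError(ValueError):
    pass


@dataclass
class ICCResult:
    icc: float
    ms_rows: float
    ms_error: float
    k: int
    category: str
    degenerate: bool = False


def icc_consistency(matrix: np.ndarray) -> ICCResult:
    """ICC(3,1) from an n-units x k-raters matrix with no missing cells."""
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ReproducibilityError("rating matrix must be 2D")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ReproducibilityError("need >= 2 units and >= 2 raters")
    if not np.isfinite(x).all():
        raise ReproducibilityError("rating matrix contains non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    # analytically a sum of squares; guard against float cancellation
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    scale = max(ss_total, 1.0)
    degenerate = ss_total == 0 or (msr + (k - 1) * mse) <= 1e-14 * scale
    if degenerate:
        return ICCResult(icc=np.nan, ms_rows=float(msr), ms_error=float(mse),
                         k=k, category="degenerate", degenerate=True)
    icc = (msr - mse) / (msr + (k - 1) * mse)
    return ICCResult(icc=float(icc), ms_rows=float(msr), ms_error=float(mse),
                     k=k, category=categorize_icc(icc), degenerate=False)


def categorize_icc(icc: float) -> str:
    """Koo-and-Li bands with good/excellent merged; 0.75 is good-to-excellent."""
    if not np.isfinite(icc):
        return "degenerate"
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    return "good_to_excellent"


def _feature_family(name: str) -> str:
    return name.split("_", 1)[0]


def reproducibility_study(feature_tables: pd.DataFrame,
                          rater_subset: tuple[str, ...] = DEFAULT_RATERS
                          ) -> pd.DataFrame:
    """Per-feature ICC across normalization arms, per grid cell.

    ``feature_tables``: long-format frame as produced by
    ``features_to_frame`` (one row per case x setting, 93 feature
    columns), restricted to one roi_kind.  ``rater_subset`` of size 2
    yields the pairwise report.

    Returns a frame with columns (feature, family, n_gray_levels,
    resampling, rater_set, icc, category, degenerate).
    """
    raters = tuple(rater_subset)
    if len(raters) < 2:
        raise ReproducibilityError("need at least 2 raters (normalization arms)")
    df = feature_tables
    have = set(df["normalization"].unique())
    missing = [r for r in raters if r not in have]
    if missing:
        raise ReproducibilityError(f"feature tables missing arms: {missing}")

    cells = df[["n_gray_levels", "resampling"]].drop_duplicates().sort_values(
        ["resampling", "n_gray_levels"]
    )
    rows = []
    rater_tag = "+".join(raters)
    for _, cell in cells.iterrows():
        nb, rs = int(cell["n_gray_levels"]), cell["resampling"]
        sub = df[(df["n_gray_levels"] == nb) & (df["resampling"] == rs)]
        pivots = {}
        for r in raters:
            arm = sub[sub["normalization"] == r].set_index("case_id")
            if arm.empty:
                raise ReproducibilityError(
                    f"missing arm {r!r} in cell (Nb={nb}, {rs})"
                )
            pivots[r] = arm
        case_ids = sorted(pivots[raters[0]].index)
        for r in raters:
            if sorted(pivots[r].index) != case_ids:
                raise ReproducibilityError(
                    f"case sets differ across arms in cell (Nb={nb}, {rs})"
                )
        for feat in FEATURE_NAMES:
            mat = np.column_stack(
                [pivots[r].loc[case_ids, feat].to_numpy(float) for r in raters]
            )
            res = icc_consistency(mat)
            rows.append({
                "feature": feat,
                "family": _feature_family(feat),
                "n_gray_levels": nb,
                "resampling": rs,
                "rater_set": rater_tag,
                "icc": res.icc,
                "category": res.category,
                "degenerate": res.degenerate,
            })
    return pd.DataFrame(rows)


def pairwise_reports(feature_tables: pd.DataFrame,
                     raters: tuple[str, ...] = DEFAULT_RATERS) -> pd.DataFrame:
    """ICC for every rater pair, concatenated (pairwise-comparison report)."""
    parts = [
        reproducibility_study(feature_tables, pair)
        for pair in itertools.combinations(raters, 2)
    ]
    return pd.concat(parts, ignore_index=True)


def summarize_report(report: pd.DataFrame) -> dict:
    """Category fractions over the 93 features and per-family mean ICC,
    per (rater_set, resampling, n_gray_levels) cell.  Degenerate features
    are excluded from fractions; their count is reported."""
    summary: dict = {}
    for (rater_set, rs, nb), sub in report.groupby(
        ["rater_set", "resampling", "n_gray_levels"]
    ):
        ok = sub[~sub["degenerate"]]
        n_ok = len(ok)
        fracs = {
            c: float((ok["category"] == c).sum() / n_ok) if n_ok else np.nan
            for c in CATEGORIES
        }
        fam_means = {
            fam: float(ok[ok["family"] == fam]["icc"].mean())
            for fam in FAMILY_NAMES
            if (ok["family"] == fam).any()
        }
        summary.setdefault(rater_set, {}).setdefault(rs, {})[int(nb)] = {
            "category_fractions": fracs,
            "n_degenerate": int(sub["degenerate"].sum()),
            "family_mean_icc": fam_means,
        }
    return summary


def write_report(report: pd.DataFrame, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "icc_report.csv", index=False)
    with open(outdir / "icc_summary.json", "w") as fh:
        json.dump(summarize_report(report), fh, indent=2, sort_keys=True)
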