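"""End-to-end orchestration: generate -> preprocess -> discretize ->
extract -> ICC / classification, with JSON manifests for reproducibility.

Every output is a pure function of (config, code version): reruns from
the same config are byte-identical.  The manifest records the
cohort-derived bin widths per (normalization x resampling) arm so any
feature value can be re-derived.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ntio
from .classifier import auc_grid, grid_to_frame
from .config import RunConfig
from .discretize import cohort_bin_width
from .features import extract_from_preprocessed, features_to_frame
from .phantom import CLASS_LABELS, PhantomCase, generate_cohort
from .preprocess import PreprocessSetting, noncystic_mask, preprocess_case
from .reproducibility import pairwise_reports, reproducibility_study, write_report

log = logging.getLogger("nephrotex")


def _derive_seed(master: int, *tokens: int) -> int:
    ss = np.random.SeedSequence([int(master), *map(int, tokens)])
    return int(ss.generate_state(1)[0] % (2**31))


def build_feature_tables(cases: list[PhantomCase], config: RunConfig,
                         roi_kinds: tuple[str, ...] | None = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Extract the 93-feature table for every grid cell.

    Preprocessing and the cohort bin width are computed once per
    (normalization x resampling) arm; the six bin counts then share that
    arm's preprocessed images.  Returns (long feature table, manifest of
    Eq.-style bin widths per arm and bin count).
    """
    roi_kinds = roi_kinds or tuple(config.roi_kinds)
    vectors = []
    schemes: dict = {}
    for norm, resamp in itertools.product(config.normalizations,
                                          config.resamplings):
        log.info("arm %s/%s: preprocessing %d cases", norm, resamp, len(cases))
        pre = []
        for case in cases:
            setting0 = PreprocessSetting(norm, resamp, config.gray_levels[0])
            img, masks, spacing = preprocess_case(case, setting0)
            pre.append((case, img, masks, spacing))
        for nb in config.gray_levels:
            scheme = cohort_bin_width([img for _, img, _, _ in pre], nb)
            schemes[f"{norm}|{resamp}|{nb}"] = {
                "normalization": norm, "resampling": resamp, "n_bins": nb,
                "range_mean": scheme.range_mean, "bin_width": scheme.bin_width,
            }
            setting = PreprocessSetting(norm, resamp, nb)
            for case, img, masks, spacing in pre:
                for roi_kind in roi_kinds:
                    if roi_kind == "noncystic":
                        roi = noncystic_mask(masks["kidney"], masks["cyst"])
                    else:
                        roi = masks["kidney"]
                    vectors.append(extract_from_preprocessed(
                        img, roi, spacing, scheme,
                        case_id=case.case_id or f"seed{case.seed}",
                        roi_kind=roi_kind, setting=setting,
                    ))
    return features_to_frame(vectors), schemes


def _labels_frame(cases: list[PhantomCase]) -> pd.DataFrame:
    return pd.DataFrame({
        "case_id": [c.case_id for c in cases],
        "class_label": [c.class_label for c in cases],
        "site_id": [c.site_id for c in cases],
    })


def run_reproducibility(config: RunConfig, outdir: str | Path | None = None):
    """Phantom cohort through the ICC reproducibility study.

    Writes feature tables, the per-feature ICC report (all-arm and
    pairwise), the JSON summary, and the run manifest.
    Returns (report frame, pairwise frame).
    """
    if len(config.normalizations) < 2:
        raise ValueError("reproducibility study needs >= 2 normalization arms")
    outdir = Path(outdir or config.outdir) / "reproducibility"
    outdir.mkdir(parents=True, exist_ok=True)
    n_half = (config.repro_n_kidneys + 1) // 2
    cases = generate_cohort(config.phantom, n_half, config.repro_n_sites,
                            _derive_seed(config.seed, 1))
    cases = cases[: config.repro_n_kidneys]
    ntio.write_cohort(cases, outdir / "phantoms")

    table, schemes = build_feature_tables(cases, config,
                                          roi_kinds=("noncystic",))
    table.to_csv(outdir / "features.csv", index=False)
    report = reproducibility_study(table, tuple(config.normalizations))
    pair = pairwise_reports(table, tuple(config.normalizations))
    write_report(pd.concat([report, pair], ignore_index=True), outdir)
    _write_manifest(outdir, config, schemes, stage="reproducibility",
                    n_cases=len(cases))
    return report, pair


def run_classification(config: RunConfig, outdir: str | Path | None = None):
    """Phantom cohort through the repeated-CV AUC grid.

    Returns the grid {(roi_kind, norm, resampling, n_bins): CVResult}.
    """
    outdir = Path(outdir or config.outdir) / "classification"
    outdir.mkdir(parents=True, exist_ok=True)
    cases = generate_cohort(config.phantom, config.clf_n_per_class,
                            config.clf_n_sites, _derive_seed(config.seed, 2))
    ntio.write_cohort(cases, outdir / "phantoms")
    labels_df = _labels_frame(cases)
    labels_df.to_csv(outdir / "labels.csv", index=False)
    y = (labels_df["class_label"] == CLASS_LABELS[0]).to_numpy(int)

    table, schemes = build_feature_tables(cases, config)
    table.to_csv(outdir / "features.csv", index=False)

    cells = {}
    order = labels_df["case_id"].tolist()
    for roi_kind, norm, resamp, nb in itertools.product(
        config.roi_kinds, config.normalizations, config.resamplings,
        config.gray_levels,
    ):
        sub = table[
            (table["roi_kind"] == roi_kind)
            & (table["normalization"] == norm)
            & (table["resampling"] == resamp)
            & (table["n_gray_levels"] == nb)
        ].set_index("case_id").loc[order]
        cells[(roi_kind, norm, resamp, nb)] = (sub, y)
    results = auc_grid(cells, folds=config.folds, repeats=config.repeats,
                       seed=_derive_seed(config.seed, 3))
    frame = grid_to_frame(results)
    frame.to_csv(outdir / "auc_grid.csv", index=False)

    sel_rows = []
    for key, res in results.items():
        for feat, cnt in sorted(res.selection_counts.items()):
            sel_rows.append({
                "roi_kind": key[0], "normalization": key[1],
                "resampling": key[2], "n_gray_levels": key[3],
                "feature": feat, "times_selected": cnt,
            })
    pd.DataFrame(sel_rows).to_csv(outdir / "selection_frequency.csv",
                                  index=False)
    _write_manifest(outdir, config, schemes, stage="classification",
                    n_cases=len(cases))
    return results


def run_all(config: RunConfig, outdir: str | Path | None = None):
    rep = run_reproducibility(config, outdir)
    grid = run_classification(config, outdir)
    return rep, grid


def _write_manifest(outdir: Path, config: RunConfig, schemes: dict,
                    stage: str, n_cases: int) -> None:
    manifest = {
        "stage": stage,
        "n_cases": n_cases,
        "master_seed": config.seed,
        "grid": {
            "normalizations": list(config.normalizations),
            "resamplings": list(config.resamplings),
            "gray_levels": list(config.gray_levels),
            "roi_kinds": list(config.roi_kinds),
        },
        "cv": {"folds": config.folds, "repeats": config.repeats,
               "interval": "95% normal-theory interval of the mean fold AUC"},
        "bin_widths": schemes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def validate_inputs(cohort_dir: str | Path) -> list[str]:
    """Machine-readable integrity check of a phantom cohort directory."""
    problems: list[str] = []
    cohort_dir = Path(cohort_dir)
    manifest_path = cohort_dir / ntio.MANIFEST_NAME
    if not manifest_path.exists():
        return [f"missing manifest: {manifest_path}"]
    manifest = pd.read_csv(manifest_path)
    labels = manifest.get("class_label")
    if labels is not None and labels.nunique() < 2:
        problems.append("label table contains fewer than 2 classes")
    for row in manifest.itertuples():
        try:
            image, spacing = ntio._read_nifti(cohort_dir / row.image_path)
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            problems.append(f"{row.case_id}: unreadable image ({exc})")
            continue
        if spacing <= 0:
            problems.append(f"{row.case_id}: non-positive pixel spacing")
        for name in ("kidney", "cyst", "psoas"):
            p = cohort_dir / getattr(row, f"{name}_path", "")
            if not p.exists():
                problems.append(f"{row.case_id}: missing {name} mask")
                continue
            m, _ = ntio._read_nifti(p)
            if m.shape != image.shape:
                problems.append(
                    f"{row.case_id}: {name} mask shape {m.shape} != "
                    f"image shape {image.shape}"
                )
    return problems
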