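"""Reading and writing phantom cases as 2D NIfTI files plus a CSV manifest."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomCase

MANIFEST_NAME = "manifest.csv"
_MASKS = ("kidney", "cyst", "psoas")


def _write_nifti(path: Path, arr: np.ndarray, spacing: float) -> None:
    img = nib.Nifti1Image(np.asarray(arr), affine=np.diag([spacing, spacing, 1, 1]))
    img.header.set_zooms((spacing, spacing))
    # fixed timestamp-free header -> byte-identical reruns
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = float(img.header.get_zooms()[0])
    return data, spacing


def write_case(case: PhantomCase, outdir: str | Path) -> dict[str, str]:
    """Write image + three masks; returns the manifest row for this case."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cid = case.case_id or f"case_seed{case.seed}"
    paths = {"image": f"{cid}_image.nii"}
    _write_nifti(outdir / paths["image"], case.image.astype(np.float64),
                 case.pixel_spacing)
    for name in _MASKS:
        fname = f"{cid}_{name}.nii"
        paths[name] = fname
        _write_nifti(outdir / fname,
                     getattr(case, f"{name}_mask").astype(np.uint8),
                     case.pixel_spacing)
    return {
        "case_id": cid,
        "class_label": case.class_label,
        "site_id": case.site_id,
        "seed": case.seed,
        **{f"{k}_path": v for k, v in paths.items()},
    }


def write_cohort(cases: list[PhantomCase], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    rows = [write_case(c, outdir) for c in cases]
    manifest = pd.DataFrame(rows)
    path = outdir / MANIFEST_NAME
    manifest.to_csv(path, index=False)
    return path


def read_cohort(indir: str | Path) -> list[PhantomCase]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / MANIFEST_NAME)
    cases = []
    for row in manifest.itertuples():
        image, spacing = _read_nifti(indir / row.image_path)
        masks = {}
        for name in _MASKS:
            m, _ = _read_nifti(indir / getattr(row, f"{name}_path"))
            masks[name] = m.astype(bool)
        case = PhantomCase(
            image=image.astype(np.float64),
            kidney_mask=masks["kidney"],
            cyst_mask=masks["cyst"],
            psoas_mask=masks["psoas"],
            pixel_spacing=spacing,
            class_label=str(row.class_label),
            site_id=int(row.site_id),
            seed=int(row.seed),
            case_id=str(row.case_id),
        )
        case.validate()
        cases.append(case)
    return cases
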