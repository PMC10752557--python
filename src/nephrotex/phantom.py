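"""Synthetic kidney MR phantoms.

Generates 2D grayscale images that emulate the statistical structure of
T2-weighted fat-saturated abdominal MRI of polycystic kidney disease:

* a kidney ellipse filled with a correlated Gaussian random-field texture
  whose correlation length depends on the genotype-like class label (the
  class-separating knob),
* hyperintense cyst disks inside the kidney,
* a hypointense psoas-muscle ellipse usable as a reference tissue for
  intensity normalization,
* a per-site affine intensity transform (scale, offset) mimicking the
  arbitrary signal scales of different scanners/sites, plus additive noise.

Every case is a pure function of ``(params, class_label, site_id, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

CLASS_LABELS = ("PKD1-like", "PKD2-like")

# Site affine maps must be shared by all cases of a site, so they are derived
# from site_id and this fixed salt, independent of the per-case seed.
_SITE_SALT = 0x5EED


class PhantomError(ValueError):
    """Raised when a phantom cannot be generated under its constraints."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry and intensity parameters of the synthetic cohort.

    Lengths are in mm, intensities in arbitrary MR-like signal units.
    ``texture_corr_length_by_class`` maps each class label to the Gaussian
    correlation length of the parenchymal texture; equal values yield a
    null (class-indistinguishable) cohort.
    """

    image_matrix: int = 320
    pixel_spacing: float = 1.25
    kidney_axes: tuple[float, float] = (90.0, 45.0)
    n_cysts: int = 8
    cyst_radius_range: tuple[float, float] = (3.0, 10.0)
    cyst_contrast: float = 2.5
    psoas_mean: float = 40.0
    psoas_sd: float = 5.0
    parenchyma_mean: float = 100.0
    parenchyma_sd: float = 15.0
    texture_corr_length_by_class: dict[str, float] = field(
        default_factory=lambda: {"PKD1-like": 2.0, "PKD2-like": 3.5}
    )
    site_scale_range: tuple[float, float] = (0.5, 2.0)
    site_offset_range: tuple[float, float] = (0.0, 50.0)
    noise_sd: float = 5.0
    background_mean: float = 8.0
    kidney_center_frac: tuple[float, float] = (0.42, 0.38)
    psoas_center_frac: tuple[float, float] = (0.78, 0.60)
    psoas_axes: tuple[float, float] = (34.0, 20.0)

    def __post_init__(self) -> None:
        if self.image_matrix <= 0:
            raise PhantomError("image_matrix must be positive")
        for name in ("pixel_spacing", "cyst_contrast", "parenchyma_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise PhantomError(f"{name} must be non-negative")
        if self.pixel_spacing <= 0:
            raise PhantomError("pixel_spacing must be positive")
        if min(self.kidney_axes) <= 0 or min(self.psoas_axes) <= 0:
            raise PhantomError("ellipse axes must be positive")
        if self.cyst_contrast <= 1:
            raise PhantomError(
                "cyst_contrast must exceed 1 (cysts are hyperintense on T2W-FS)"
            )
        if self.psoas_mean >= self.parenchyma_mean:
            raise PhantomError(
                "psoas_mean must be below parenchyma_mean (muscle is hypointense)"
            )
        if self.cyst_radius_range[0] <= 0 or (
            self.cyst_radius_range[1] < self.cyst_radius_range[0]
        ):
            raise PhantomError("cyst_radius_range must be a positive ordered pair")
        missing = [c for c in CLASS_LABELS if c not in self.texture_corr_length_by_class]
        if missing:
            raise PhantomError(f"texture_corr_length_by_class missing {missing}")


@dataclass
class PhantomCase:
    """One synthetic subject: image, masks, and provenance."""

    image: np.ndarray
    kidney_mask: np.ndarray
    cyst_mask: np.ndarray
    psoas_mask: np.ndarray
    pixel_spacing: float
    class_label: str
    site_id: int
    seed: int
    case_id: str = ""

    def validate(self) -> None:
        shp = self.image.shape
        for name in ("kidney_mask", "cyst_mask", "psoas_mask"):
            m = getattr(self, name)
            if m.shape != shp:
                raise PhantomError(f"{name} shape {m.shape} != image shape {shp}")
            if not np.isin(m, (0, 1)).all():
                raise PhantomError(f"{name} is not binary")
        if (self.cyst_mask & ~self.kidney_mask).any():
            raise PhantomError("cyst_mask must be a subset of kidney_mask")
        if (self.psoas_mask & self.kidney_mask).any():
            raise PhantomError("psoas_mask must not intersect kidney_mask")
        if not (self.kidney_mask & ~self.cyst_mask).any():
            raise PhantomError("noncystic parenchyma (kidney minus cysts) is empty")

    @property
    def noncystic_mask(self) -> np.ndarray:
        return self.kidney_mask & ~self.cyst_mask


def _ellipse_mask(n: int, center_px: tuple[float, float],
                  semi_axes_px: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    d = ((rr - center_px[0]) / semi_axes_px[0]) ** 2 + (
        (cc - center_px[1]) / semi_axes_px[1]
    ) ** 2
    return d <= 1.0


def _correlated_field(rng: np.random.Generator, n: int, sigma_px: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian random field, Gaussian autocorrelation."""
    white = rng.standard_normal((n, n))
    if sigma_px <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma_px, mode="wrap")
    sd = f.std()
    if sd == 0:  # pragma: no cover - only for pathological sigma
        return white
    return f / sd


def site_affine(params: PhantomParams, site_id: int) -> tuple[float, float]:
    """Per-site intensity transform (scale, offset), a pure function of site_id."""
    rng = np.random.default_rng(np.random.SeedSequence([_SITE_SALT, int(site_id)]))
    scale = rng.uniform(*params.site_scale_range)
    offset = rng.uniform(*params.site_offset_range)
    return float(scale), float(offset)


def _place_cysts(rng: np.random.Generator, params: PhantomParams,
                 kidney: np.ndarray) -> np.ndarray:
    n = params.image_matrix
    cysts = np.zeros((n, n), dtype=bool)
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    for _ in range(params.n_cysts):
        radius_mm = rng.uniform(*params.cyst_radius_range)
        radius_px = radius_mm / params.pixel_spacing
        # candidate centers: kidney eroded so the full disk stays inside
        erosion_iter = max(1, int(np.ceil(radius_px)))
        allowed = ndimage.binary_erosion(kidney, iterations=erosion_iter)
        placed = False
        for _attempt in range(1000):
            r = rng.uniform(0, n)
            c = rng.uniform(0, n)
            if allowed[min(int(r), n - 1), min(int(c), n - 1)]:
                cysts |= (rr - r) ** 2 + (cc - c) ** 2 <= radius_px**2
                placed = True
                break
        if not placed:
            raise PhantomError(
                "could not place a cyst of radius "
                f"{radius_mm:.2f} mm inside the kidney after 1000 retries "
                "(cyst must lie fully within the kidney mask)"
            )
    return cysts & kidney


def generate_subject_phantom(params: PhantomParams, class_label: str,
                             site_id: int, seed: int) -> PhantomCase:
    """Generate one deterministic phantom case.

    The base (pre-site-transform) image satisfies
    mean(cysts) > mean(noncystic parenchyma) > mean(psoas); the returned
    image is ``site_scale * base + site_offset + noise``.
    """
    if class_label not in params.texture_corr_length_by_class:
        raise PhantomError(f"unknown class label {class_label!r}")
    n = params.image_matrix
    sp = params.pixel_spacing
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))

    kidney = _ellipse_mask(
        n,
        (params.kidney_center_frac[0] * n, params.kidney_center_frac[1] * n),
        (params.kidney_axes[0] / 2 / sp, params.kidney_axes[1] / 2 / sp),
    )
    psoas = _ellipse_mask(
        n,
        (params.psoas_center_frac[0] * n, params.psoas_center_frac[1] * n),
        (params.psoas_axes[0] / 2 / sp, params.psoas_axes[1] / 2 / sp),
    )
    if (kidney & psoas).any():
        raise PhantomError("kidney and psoas ellipses overlap; adjust geometry")
    if not kidney.any() or not psoas.any():
        raise PhantomError("kidney or psoas ellipse is empty at this geometry")

    corr_len_mm = params.texture_corr_length_by_class[class_label]
    texture = _correlated_field(rng, n, corr_len_mm / sp)
    cysts = _place_cysts(rng, params, kidney)

    base = np.full((n, n), params.background_mean, dtype=np.float64)
    base += 0.25 * params.noise_sd * rng.standard_normal((n, n))  # faint bg texture
    base[kidney] = params.parenchyma_mean + params.parenchyma_sd * texture[kidney]
    base[cysts] = params.cyst_contrast * params.parenchyma_mean
    base[psoas] = params.psoas_mean + params.psoas_sd * rng.standard_normal(
        int(psoas.sum())
    )

    noncystic = kidney & ~cysts
    if cysts.any():
        assert base[cysts].mean() > base[noncystic].mean() > base[psoas].mean()
    else:
        assert base[noncystic].mean() > base[psoas].mean()

    scale, offset = site_affine(params, site_id)
    image = scale * base + offset + params.noise_sd * rng.standard_normal((n, n))

    case = PhantomCase(
        image=image.astype(np.float64),
        kidney_mask=kidney,
        cyst_mask=cysts,
        psoas_mask=psoas,
        pixel_spacing=sp,
        class_label=class_label,
        site_id=int(site_id),
        seed=int(seed),
    )
    case.validate()
    return case


def derive_case_seed(master_seed: int, case_index: int) -> int:
    """Reproducible per-case seed (< 2**31) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(case_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def cohort_layout(n_per_class: int, n_sites: int) -> list[tuple[str, int]]:
    """(class, site) assignments: classes balanced, sites round-robin and
    identical across classes so the cohort is site-matched."""
    layout = []
    for i in range(n_per_class):
        site = i % n_sites
        for label in CLASS_LABELS:
            layout.append((label, site))
    return layout


def generate_cohort(params: PhantomParams, n_per_class: int, n_sites: int,
                    seed: int) -> list[PhantomCase]:
    """Generate a balanced, site-matched cohort of ``2 * n_per_class`` cases."""
    if n_per_class < 1:
        raise PhantomError("n_per_class must be >= 1")
    if n_sites < 1:
        raise PhantomError("n_sites must be >= 1")
    cases = []
    for idx, (label, site) in enumerate(cohort_layout(n_per_class, n_sites)):
        case = generate_subject_phantom(
            params, label, site, derive_case_seed(seed, idx)
        )
        case.case_id = f"case{idx:04d}"
        cases.append(case)
    return cases
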