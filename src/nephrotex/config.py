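"""Run configuration: the preprocessing grid, cohort sizes, CV parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .phantom import PhantomParams
from .preprocess import GRAY_LEVELS, NORMALIZATIONS, RESAMPLINGS


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, including the master seed."""

    seed: int
    outdir: str = "runs/default"
    phantom: PhantomParams = field(default_factory=PhantomParams)
    normalizations: tuple[str, ...] = NORMALIZATIONS
    resamplings: tuple[str, ...] = RESAMPLINGS
    gray_levels: tuple[int, ...] = GRAY_LEVELS
    roi_kinds: tuple[str, ...] = ("noncystic", "entire_kidney")
    folds: int = 5
    repeats: int = 10
    # reproducibility cohort (single-scan study role)
    repro_n_kidneys: int = 29
    repro_n_sites: int = 7
    # classification cohort (multi-site matched study role)
    clf_n_per_class: int = 68
    clf_n_sites: int = 7

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is mandatory")
        self.seed = int(self.seed)
        bad = [n for n in self.normalizations if n not in NORMALIZATIONS]
        if bad:
            raise ConfigError(f"unknown normalizations {bad}")
        bad = [r for r in self.resamplings if r not in RESAMPLINGS]
        if bad:
            raise ConfigError(f"unknown resamplings {bad}")
        if any(g < 2 for g in self.gray_levels):
            raise ConfigError("gray levels must be >= 2")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("config must provide a seed")
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            for key in ("kidney_axes", "cyst_radius_range", "site_scale_range",
                        "site_offset_range", "kidney_center_frac",
                        "psoas_center_frac", "psoas_axes"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomParams(**ph)
        for key in ("normalizations", "resamplings", "gray_levels", "roi_kinds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
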