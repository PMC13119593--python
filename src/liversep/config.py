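"""Pipeline configuration: YAML-backed, validated before any compute."""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from pathlib import Path

import yaml

from .acquisition import AcquisitionParams
from .phantom import CohortSpec
from .separation import SeparationConfig


@dataclass
class PipelineConfig:
    out_dir: Path = Path("results")
    seed: int = 1
    grid_shape: tuple = (48, 48, 24)
    acq: AcquisitionParams = dfield(default_factory=AcquisitionParams)
    cohort: CohortSpec = dfield(default_factory=CohortSpec)
    separation: SeparationConfig = dfield(default_factory=SeparationConfig)
    grid_lo: float = 50.0
    grid_hi: float = 300.0
    grid_step: float = 1.0
    mask_threshold: float = 15.0
    erosion_radius: int = 1
    balloon_r2s_max: float = 5.0
    medi_lambda: float = 1e-3
    stats_method: str = "normal"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        errors = []
        if self.grid_step <= 0:
            errors.append("grid_step: must be positive")
        if self.grid_lo <= 0 or self.grid_hi < self.grid_lo:
            errors.append("grid_lo/grid_hi: need 0 < grid_lo <= grid_hi")
        if self.mask_threshold <= 0:
            errors.append("mask_threshold: must be positive")
        if self.erosion_radius < 0:
            errors.append("erosion_radius: must be >= 0")
        if self.stats_method not in ("normal", "exact"):
            errors.append("stats_method: must be 'normal' or 'exact'")
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "acquisition" in kwargs:
            kwargs["acq"] = AcquisitionParams.from_dict(kwargs.pop("acquisition"))
        if "cohort" in kwargs:
            c = kwargs.pop("cohort")
            for key in ("counts", "chi_neg_mean", "chi_neg_sd", "chi_pos_mean",
                        "chi_pos_sd"):
                if key in c:
                    c[key] = tuple(c[key])
            if "fat_fraction_range" in c:
                c["fat_fraction_range"] = tuple(tuple(x) for x in
                                                c["fat_fraction_range"])
            kwargs["cohort"] = CohortSpec(**c)
        if "separation" in kwargs:
            kwargs["separation"] = SeparationConfig(**kwargs.pop("separation"))
        return cls(**kwargs)
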