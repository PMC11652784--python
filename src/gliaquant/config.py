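"""Run configuration with validated, literature-sourced defaults.

Defaults are the pipeline's published operating points: glial channels are
thresholded at 30–255 and plaque channels at 20–255 (8-bit, inclusive, no
shade correction); plaque neighborhoods span 8x the Feret diameter; fold
cutoffs are ±2 (inclusive); perturbagen score screens keep scores strictly
above 80 (classes) or 90 (compounds); significance is alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    cell_threshold_low: int = 30
    cell_threshold_high: int = 255
    plaque_threshold_low: int = 20
    plaque_threshold_high: int = 255
    min_cell_area_px: int = 30
    min_plaque_area_px: int = 20
    neighborhood_factor: float = 8.0
    fold_up_cut: float = 2.0
    fold_down_cut: float = -2.0
    pcl_score_cut: float = 80.0
    pc_score_cut: float = 90.0
    alpha: float = 0.05
    sgz_band_um: float = 20.0
    seed: int = 0
    pixel_size_um: float = 1.0
    output_dir: str = "gliaquant_out"
    stages: tuple[str, ...] = ("morpho", "plaque", "neuro", "sig", "metab")

    def __post_init__(self) -> None:
        for name in ("cell_threshold_low", "cell_threshold_high", "plaque_threshold_low", "plaque_threshold_high"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.cell_threshold_low > self.cell_threshold_high:
            raise ValueError("cell threshold low exceeds high")
        if self.plaque_threshold_low > self.plaque_threshold_high:
            raise ValueError("plaque threshold low exceeds high")
        if self.neighborhood_factor <= 0:
            raise ValueError("neighborhood_factor must be positive")
        if self.fold_up_cut < 1 or self.fold_down_cut > -1:
            raise ValueError("fold cutoffs must satisfy up >= 1, down <= -1")
        for name in ("pcl_score_cut", "pc_score_cut"):
            if not -100 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} outside [-100, 100]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.sgz_band_um <= 0:
            raise ValueError("sgz_band_um must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d
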