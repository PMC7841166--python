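"""Pipeline configuration: every tunable, with its default, in one place.

Configs are flat YAML files; unknown keys are rejected so a typo cannot
silently fall back to a default.  The effective configuration is echoed to
the output directory of every CLI run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .motility import MotilityParams
from .profiles import MeasurementParams
from .segmentation import SegmentationParams


@dataclass
class PipelineConfig:
    pixel_pitch_nm: float = 40.0
    z_step_nm: float = 110.0
    z_indices: list | None = None        # None = all slices
    channel_shift: tuple = (0, 0)        # optional integer (dr, dc) red shift
    sigma_low: float = 1.0
    sigma_high: float = 5.0
    min_area: int = 50
    max_area: int = 5000
    segmentation_source: str = "mean"
    termination_frac: float = 0.30
    termination_box: int = 3
    max_axis_extension: int = 50
    median_window: int = 5
    threshold_frac: float = 0.40
    max_gap: int = 4
    bin_nm: float = 80.0
    alpha: float = 0.05
    motion_threshold_nm: float = 200.0
    near_edge_threshold_nm: float = 2000.0
    smoothing_window_px: int = 15
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.channel_shift = tuple(cfg.channel_shift)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @property
    def segmentation(self) -> SegmentationParams:
        return SegmentationParams(self.sigma_low, self.sigma_high,
                                  self.min_area, self.max_area,
                                  self.segmentation_source)

    @property
    def measurement(self) -> MeasurementParams:
        return MeasurementParams(self.threshold_frac, self.max_gap,
                                 self.median_window, self.termination_frac,
                                 self.termination_box, self.max_axis_extension)

    @property
    def motility(self) -> MotilityParams:
        return MotilityParams(self.motion_threshold_nm,
                              self.near_edge_threshold_nm,
                              self.smoothing_window_px)
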