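"""Structured pipeline configuration (YAML file + CLI overrides)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .pipeline import AnalysisConfig
from .solar_clock import SolarContext
from .stopover_segmentation import SegmentationConfig
from .synthetic_data import SimConfig


class ConfigError(ValueError):
    """Schema violation; message names the offending field."""


@dataclass
class PipelineConfig:
    seed: int = 1
    simulation: SimConfig = field(default_factory=SimConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> "PipelineConfig":
        s = self.segmentation
        checks = [
            ("segmentation.radius_min_m", s.radius_min_m > 0),
            ("segmentation.radius_step_m", s.radius_step_m > 0),
            ("segmentation.radius_max_m", s.radius_max_m >= s.radius_min_m),
            ("segmentation.min_duration_h", s.min_duration_h >= 0),
            ("segmentation.min_daylight_frac", 0 <= s.min_daylight_frac <= 1),
            ("segmentation.buffer_min_points", s.buffer_min_points >= 1),
            ("segmentation.buffer_km", s.buffer_km > 0),
            ("segmentation.activity_speed_kmh", s.activity_speed_kmh >= 0),
            ("analysis.loess_span", 0 < self.analysis.loess_span <= 1),
            ("analysis.correlation_threshold",
             0 < self.analysis.correlation_threshold < 1),
            ("analysis.window_before_h", self.analysis.window_before_h >= 1),
            ("analysis.window_after_h", self.analysis.window_after_h >= 1),
            ("analysis.max_mean_interval_h",
             self.analysis.max_mean_interval_h > 0),
            ("seed", isinstance(self.seed, int)),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid config field: {name}")
        return self


def _apply_section(obj, section: dict, prefix: str):
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, val in section.items():
        if key not in valid:
            raise ConfigError(f"unknown config field: {prefix}.{key}")
        if key == "solar" and isinstance(val, dict):
            val = SolarContext(**val)
        if isinstance(val, list):
            val = tuple(val)
        setattr(obj, key, val)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load YAML config; unknown keys fail with the field name."""
    cfg = PipelineConfig()
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    for section_name, target in (("simulation", cfg.simulation),
                                 ("segmentation", cfg.segmentation),
                                 ("analysis", cfg.analysis)):
        section = data.pop(section_name, {})
        if section:
            if not isinstance(section, dict):
                raise ConfigError(f"invalid config field: {section_name}")
            _apply_section(target, section, section_name)
    if "seed" in data:
        cfg.seed = int(data.pop("seed"))
    if data:
        raise ConfigError(f"unknown config field: {sorted(data)[0]}")
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        section, _, name = key.partition(".")
        if not name:
            setattr(cfg, section, val)
        else:
            _apply_section(getattr(cfg, section), {name: val}, section)
    cfg.simulation.seed = cfg.seed
    return cfg.validate()
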