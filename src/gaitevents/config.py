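"""Pipeline configuration: one YAML file with per-module sections.

Unknown keys are rejected so that typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigError


@dataclass
class DenoiseConfig:
    levels: int = 4              # dyadic scales analysed for modulus maxima
    wavelet: str = "db2"
    beta_threshold: float = 0.0  # chains with beta_hat >= this are kept

    def validate(self):
        if self.levels < 2:
            raise ConfigError("denoise.levels must be >= 2")


@dataclass
class SegmentationConfig:
    r: float = 0.05              # threshold = r * max(smoothed jerk)
    window_ms: float = 30.0      # trailing smoothing window (30 ms)
    min_segment_ms: float = 50.0

    def validate(self):
        if not 0 < self.r < 1:
            raise ConfigError("segmentation.r must lie in (0, 1)")
        if self.window_ms <= 0:
            raise ConfigError("segmentation.window_ms must be positive")
        if self.min_segment_ms < 0:
            raise ConfigError("segmentation.min_segment_ms must be >= 0")


@dataclass
class IntegrationConfig:
    highpass_hz: float = 0.1
    detrend_levels: int = 8
    detrend_basis: str = "sym8"       # db6 selectable
    soft_threshold_mode: str = "approx_only"  # or "approx_and_details"
    trend_fs: float = 100.0           # rate at which the trend is estimated

    def validate(self):
        if self.highpass_hz < 0:
            raise ConfigError("integration.highpass_hz must be >= 0")
        if self.detrend_levels < 1:
            raise ConfigError("integration.detrend_levels must be >= 1")
        if self.soft_threshold_mode not in ("approx_only", "approx_and_details"):
            raise ConfigError(
                "integration.soft_threshold_mode must be 'approx_only' or "
                "'approx_and_details'"
            )
        if self.trend_fs <= 0:
            raise ConfigError("integration.trend_fs must be positive")


@dataclass
class EventsConfig:
    # Slope gates quantify "drops/rises sharply".  Genuine strike/off slopes
    # are 0.3-0.5 m/s; the residual baseline wobble left by trend removal has
    # slopes up to ~0.1 m/s on records of a few tens of seconds, so the gate
    # sits between the two populations.
    slope_window_ms: float = 50.0
    drop_slope_thresh: float = 0.15   # m/s, "drops sharply"
    rise_slope_thresh: float = 0.15   # m/s, "rises sharply"
    search_margin_ms: float = 100.0

    def validate(self):
        if self.slope_window_ms <= 0:
            raise ConfigError("events.slope_window_ms must be positive")
        if self.drop_slope_thresh < 0 or self.rise_slope_thresh < 0:
            raise ConfigError("events slope thresholds must be >= 0")
        if self.search_margin_ms < 0:
            raise ConfigError("events.search_margin_ms must be >= 0")


@dataclass
class ValidationConfig:
    max_gap_ms: float = 100.0

    def validate(self):
        if self.max_gap_ms <= 0:
            raise ConfigError("validation.max_gap_ms must be positive")


@dataclass
class SyntheticConfig:
    """Generator parameters; mirrors synthetic.GaitParams defaults."""

    cycle_s: float = 1.0
    n_cycles: int = 10
    stance_fraction: float = 0.6
    swing_peak_heel_m: float = 0.15
    swing_peak_toe_m: float = 0.05
    event_phases: tuple = (0.0, 0.12, 0.45, 0.62)
    noise_sigma: float = 0.2
    drift_amp: float = 0.1
    fs_accel: float = 1000.0
    fs_ref: float = 100.0
    seed: int = 0

    def validate(self):
        from .synthetic import GaitParams

        GaitParams(**dataclasses.asdict(self))  # delegates range checks


@dataclass
class PipelineConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    events: EventsConfig = field(default_factory=EventsConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self):
        for section in dataclasses.fields(self):
            getattr(self, section.name).validate()
        return self


_SECTIONS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def default_config() -> PipelineConfig:
    return PipelineConfig().validate()


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config; missing sections/keys fall back to defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping of sections")
    cfg = PipelineConfig()
    for section, content in raw.items():
        if section not in _SECTIONS:
            raise ConfigError(f"{path}: unknown config section {section!r}")
        if content is None:
            continue
        if not isinstance(content, dict):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        target = getattr(cfg, section)
        known = {f.name for f in dataclasses.fields(target)}
        for key, value in content.items():
            if key not in known:
                raise ConfigError(
                    f"{path}: unknown key {key!r} in section {section!r}"
                )
            if key == "event_phases":
                value = tuple(value)
            setattr(target, key, value)
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    data["synthetic"]["event_phases"] = list(data["synthetic"]["event_phases"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
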