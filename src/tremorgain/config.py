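"""Run configuration: every tunable of the pipeline in one flat record.

Defaults equal the protocol's printed values wherever one exists (sampling
rates, gains, tone anchors, filter band, analysis bands, baseline window,
kernel span); everything else is the package's documented choice.  The
config serialises to a flat key-value YAML file and is copied verbatim
into every output directory so a run can be reproduced from its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .protocol import FeedbackConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a config file."""


@dataclass
class RunConfig:
    # stream geometry
    force_fs_hz: float = 80.0
    pupil_fs_hz: float = 240.0
    rest_duration_s: float = 30.0
    task_duration_s: float = 30.0

    # feedback protocol
    gain_low: float = 0.04
    gain_high: float = 6.9
    audio_gain_low: float = 1.0
    audio_gain_high: float = 172.5
    tone_target_hz: float = 440.0
    tone_min_hz: float = 120.0
    tone_max_hz: float = 880.0
    viewing_distance_cm: float = 90.0

    # force filtering / spectra
    filter_order: int = 5
    filter_low_hz: float = 0.1
    filter_high_hz: float = 12.0
    welch_window_s: float = 4.0
    welch_overlap: float = 0.5
    tremor_band_lo_hz: float = 4.0
    tremor_band_hi_hz: float = 12.0
    voluntary_band_lo_hz: float = 0.0
    voluntary_band_hi_hz: float = 3.0

    # pupil preprocessing
    conf_threshold: float = 0.6
    accel_z_threshold: float = 3.0
    blink_pad_s: float = 0.1
    kernel_span_samples: int = 120
    baseline_start_s: float = -10.0
    baseline_end_s: float = -2.0
    max_nan_fraction: float = 0.5

    # statistics
    alpha: float = 0.05
    contrast_unit: str = "trial_pair"  # or "participant"
    holm_correction: bool = False

    # cohort simulation
    simulate: bool = True
    n_per_group: int = 14
    effects_preset: str = "default"  # or "null" (zero-effect calibration cohort)
    feedback_weight_vo: float = 1.0
    feedback_weight_va: float = 1.2
    feedback_weight_ao: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.force_fs_hz <= 2 * self.filter_high_hz:
            raise ConfigError("force sampling rate must exceed twice the filter high cut")
        if self.contrast_unit not in ("trial_pair", "participant"):
            raise ConfigError(f"unknown contrast unit {self.contrast_unit!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")

    # -- derived views -------------------------------------------------
    def feedback_config(self) -> FeedbackConfig:
        return FeedbackConfig(
            gain_low=self.gain_low,
            gain_high=self.gain_high,
            tone_target_hz=self.tone_target_hz,
            tone_min_hz=self.tone_min_hz,
            tone_max_hz=self.tone_max_hz,
            audio_gain_low=self.audio_gain_low,
            audio_gain_high=self.audio_gain_high,
            viewing_distance_cm=self.viewing_distance_cm,
        )

    @property
    def feedback_weights(self) -> dict[str, float]:
        return {
            "vo": self.feedback_weight_vo,
            "va": self.feedback_weight_va,
            "ao": self.feedback_weight_ao,
        }

    # -- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a flat key-value mapping")
        return cls.from_dict(data)
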