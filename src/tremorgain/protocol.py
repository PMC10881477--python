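"""Experiment protocol: force calibration, feedback mappings and trial scheduling.

The task is an isometric pinch-force tracking paradigm: the participant
presses a force sensor between thumb and index finger to match a target
force of 15% of their individually calibrated maximum (MaxF) and holds it
for 30 s per trial.  The deviation between produced and target force is
fed back visually (cursor position on screen), auditorily (pitch of a
second tone against a constant 440 Hz reference) or both, and the
*feedback gain* scales the displayed/heard deviation without changing the
force actually required.  A session comprises 12 trials: three fixed-order
blocks (visual-only, audio-visual, auditory-only) of four trials each,
with two low-gain and two high-gain trials randomised within each block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FEEDBACK_TYPES",
    "GAIN_LEVELS",
    "CalibrationError",
    "CalibrationResult",
    "FeedbackConfig",
    "TrialSpec",
    "compute_max_force",
    "target_force",
    "feedback_position",
    "tone_frequency",
    "build_schedule",
]

#: Fixed block order of the three sensory feedback modalities.
FEEDBACK_TYPES: tuple[str, ...] = ("vo", "va", "ao")
GAIN_LEVELS: tuple[str, ...] = ("low", "high")

#: Fraction of MaxF used as the target force.
TARGET_FRACTION = 0.15


class CalibrationError(ValueError):
    """Raised when maximum-force calibration input is malformed."""


@dataclass(frozen=True)
class CalibrationResult:
    """Maximum voluntary pinch force and the derived target force."""

    maxf: float

    def __post_init__(self) -> None:
        if not self.maxf > 0:
            raise CalibrationError(f"MaxF must be positive, got {self.maxf}")

    @property
    def target_force(self) -> float:
        return TARGET_FRACTION * self.maxf


@dataclass(frozen=True)
class FeedbackConfig:
    """Gains and tone anchors of the feedback mappings.

    Visual gains are stored as dimensionless multipliers numerically equal
    to the visual angles used on screen (0.04 low, 6.9 high); the
    screen-geometry conversion (viewing distance, pixel pitch) is carried
    as optional metadata and not used by the analysis.  Audio gains default
    to 1 for the low and to the visual high:low ratio (6.9/0.04 = 172.5)
    for the high level.
    """

    gain_low: float = 0.04
    gain_high: float = 6.9
    tone_target_hz: float = 440.0
    tone_min_hz: float = 120.0
    tone_max_hz: float = 880.0
    audio_gain_low: float = 1.0
    audio_gain_high: float = 6.9 / 0.04
    viewing_distance_cm: float | None = 90.0

    def __post_init__(self) -> None:
        if not (self.tone_min_hz < self.tone_target_hz < self.tone_max_hz):
            raise ValueError("tone anchors must satisfy min < target < max")
        if not self.gain_low < self.gain_high:
            raise ValueError("gain_low must be below gain_high")

    def gain(self, level: str) -> float:
        return {"low": self.gain_low, "high": self.gain_high}[level]

    def audio_gain(self, level: str) -> float:
        return {"low": self.audio_gain_low, "high": self.audio_gain_high}[level]


@dataclass(frozen=True)
class TrialSpec:
    """One trial's condition and timing."""

    index: int
    feedback_type: str
    gain_level: str
    rest_duration: float = 30.0
    task_duration: float = 30.0

    def __post_init__(self) -> None:
        if self.feedback_type not in FEEDBACK_TYPES:
            raise ValueError(f"unknown feedback type {self.feedback_type!r}")
        if self.gain_level not in GAIN_LEVELS:
            raise ValueError(f"unknown gain level {self.gain_level!r}")
        if not 1 <= self.index <= 12:
            raise ValueError(f"trial index must be in 1..12, got {self.index}")


def compute_max_force(presses, fs: float) -> float:
    """MaxF from three maximum-pressure presses.

    Each press trace must cover at least 1 s at sampling rate ``fs``; the
    per-press mean is taken over exactly the first 1 s window
    (``round(fs)`` samples) and MaxF is the maximum of the three means.
    """
    presses = [np.asarray(p, dtype=float) for p in presses]
    if len(presses) != 3:
        raise CalibrationError(f"calibration needs exactly 3 presses, got {len(presses)}")
    n = int(round(fs * 1.0))
    means = []
    for i, p in enumerate(presses):
        if p.size < n:
            raise CalibrationError(
                f"press {i + 1} covers {p.size / fs:.3f} s, needs >= 1 s"
            )
        means.append(float(np.mean(p[:n])))
    return max(means)


def target_force(maxf: float) -> float:
    """Target force: 15% of MaxF."""
    if not maxf > 0:
        raise CalibrationError(f"MaxF must be positive, got {maxf}")
    return TARGET_FRACTION * maxf


def feedback_position(f_p, f_t: float, g: float):
    """Displayed cursor position for produced force ``f_p``.

    position = (f_p - f_t) * g + f_t: the cursor aligns with the target
    bar exactly when the produced force equals the target force, for any
    gain.  Affine in f_p with slope g; accepts scalars or arrays.
    """
    if not f_t > 0:
        raise ValueError("target force must be positive")
    return (np.asarray(f_p, dtype=float) - f_t) * g + f_t


def tone_frequency(f_p, f_t: float, audio_gain: float, cfg: FeedbackConfig | None = None):
    """Pitch of the varying feedback tone, in Hz.

    The pitch is linearly related to the signed distance between produced
    and target force: at the target the tone matches the 440 Hz reference;
    zero force at unit audio gain maps to the lower anchor (120 Hz).  The
    output is clipped to the audible range [tone_min_hz, tone_max_hz].
    """
    if cfg is None:
        cfg = FeedbackConfig()
    if not f_t > 0:
        raise ValueError("target force must be positive")
    if audio_gain < 0:
        raise ValueError("audio gain must be non-negative")
    slope = (cfg.tone_target_hz - cfg.tone_min_hz) / f_t
    raw = cfg.tone_target_hz + slope * audio_gain * (np.asarray(f_p, dtype=float) - f_t)
    return np.clip(raw, cfg.tone_min_hz, cfg.tone_max_hz)


def build_schedule(
    seed: int,
    rest_duration: float = 30.0,
    task_duration: float = 30.0,
) -> list[TrialSpec]:
    """Seeded 12-trial schedule.

    Blocks follow the fixed modality order vo, va, ao; within each block of
    four, the gain levels are a seeded random permutation of
    {low, low, high, high}.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []
    index = 1
    for ftype in FEEDBACK_TYPES:
        gains = list(rng.permutation(["low", "low", "high", "high"]))
        for g in gains:
            trials.append(
                TrialSpec(
                    index=index,
                    feedback_type=ftype,
                    gain_level=str(g),
                    rest_duration=rest_duration,
                    task_duration=task_duration,
                )
            )
            index += 1
    return trials
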