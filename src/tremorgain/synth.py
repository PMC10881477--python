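"""Synthetic cohorts: virtual participants and multi-stream session recordings.

The generator emulates the statistical structure the analysis chain
assumes, not tremor mechanism.  A virtual participant carries a maximum
pinch force, a tremor oscillation in the 4-12 Hz action-tremor band whose
amplitude grows under high feedback gain (by a group- and
modality-dependent fraction), slow voluntary tracking drift below 3 Hz,
sensor noise, a pupil baseline with condition-dependent task-evoked
dilation, and blink behaviour.  Two generation paths exist:

* the *stream* path renders full 80 Hz force / 240 Hz pupil / marker
  recordings (``simulate_cohort``) for end-to-end pipeline tests, and
* the *feature* path draws per-trial scalar outcomes directly from the
  same statistical model (``simulate_trial_features``) for
  calibration-scale experiments (type-I error, power, pattern recovery)
  where thousands of cohorts are needed.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import FEEDBACK_TYPES, TrialSpec, build_schedule, target_force

__all__ = [
    "VirtualParticipant",
    "StreamSet",
    "GroupEffects",
    "CohortEffects",
    "DEFAULT_FEEDBACK_WEIGHTS",
    "PUPIL_RAMP_RISE_S",
    "pupil_ramp_mean",
    "draw_participant",
    "simulate_force_trial",
    "simulate_pupil_trial",
    "simulate_session",
    "simulate_cohort",
    "simulate_trial_features",
    "participants_frame",
]

#: Relative weight of the high-gain tremor boost per feedback modality.
#: The combined audio-visual condition carries the strongest effect.
DEFAULT_FEEDBACK_WEIGHTS: dict[str, float] = {"vo": 1.0, "va": 1.2, "ao": 1.0}

#: Seconds the task-evoked pupil dilation takes to reach its plateau.
PUPIL_RAMP_RISE_S = 5.0

#: Trial-mean standard deviation of the baseline-corrected pupil mean (mm)
#: implied by the slow pupil noise model; used by the feature-level path.
PUPIL_TRIAL_MEAN_SD = 0.025

#: Relative spread of the realised within-trial drift power around its
#: nominal value (low-frequency drift has few independent cycles per 30 s).
DRIFT_POWER_REL_SD = 0.18


def pupil_ramp_mean(task_duration_s: float = 30.0, rise_s: float = PUPIL_RAMP_RISE_S) -> float:
    """Mean of the dilation ramp template over the task window (analytic)."""
    return 1.0 - rise_s / (2.0 * task_duration_s)


@dataclass
class VirtualParticipant:
    """Ground-truth parameters driving one simulated participant."""

    pid: str
    group: str  # "pET" or "HC"
    maxf: float
    tremor_freq_hz: float
    tremor_amp0: float  # baseline tremor amplitude, normalized force units
    gain_beta: dict  # feedback type -> fractional amplitude increase under high gain
    drift_amp: float = 0.05  # normalized units, std of voluntary drift
    drift_cutoff_hz: float = 1.5
    noise_sd: float = 0.005  # normalized units, white sensor noise
    pupil_base_mm: float = 4.0
    pupil_arousal_mm: dict = field(default_factory=dict)  # (type, gain) -> mm
    pupil_noise_sd: float = 0.05  # mm, slow pupil noise
    blink_rate_hz: float = 0.08  # blink suppression during demanding tracking
    blink_dur_s: float = 0.2
    age: float = 65.0
    tetras: float = 0.0
    bdi: float = 0.0

    def __post_init__(self) -> None:
        if not 4.0 <= self.tremor_freq_hz <= 12.0:
            raise ValueError("tremor frequency must lie in the 4-12 Hz band")
        if self.tremor_amp0 < 0 or self.blink_dur_s <= 0:
            raise ValueError("tremor_amp0 must be >= 0 and blink_dur_s > 0")
        if any(b < 0 for b in self.gain_beta.values()):
            raise ValueError("gain sensitivity must be non-negative")

    @property
    def f_t(self) -> float:
        return target_force(self.maxf)


@dataclass
class StreamSet:
    """Timestamped force, pupil and marker streams for one session."""

    force: pd.DataFrame  # time_s, force
    pupil: pd.DataFrame  # time_s, diameter_mm, confidence, gaze_x, gaze_y
    markers: pd.DataFrame  # time_s, label, trial_index, feedback_type, gain_level
    schedule: list = field(default_factory=list)
    blink_truth: list = field(default_factory=list)  # (start_s, end_s) session time

    def validate(self) -> None:
        for name in ("force", "pupil"):
            t = getattr(self, name)["time_s"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} timestamps are not strictly increasing")


# ---------------------------------------------------------------------------
# group-level effect distributions
# ---------------------------------------------------------------------------

@dataclass
class GroupEffects:
    """Sampling distributions of participant parameters for one group.

    Multiplicative parameters (tremor amplitude, gain sensitivity, pupil
    reactivity) are lognormal around their medians; a median of exactly 0
    yields exactly 0 (a true null for that condition).
    """

    tremor_amp0_median: float
    tremor_amp0_sigma: float
    gain_beta_median: dict  # per feedback type
    gain_beta_sigma: float
    pupil_delta_median: dict  # per feedback type, high - low arousal (mm)
    pupil_delta_sigma: float
    pupil_arousal_low_mm: float = 0.1
    pupil_reactivity_sigma: float = 0.2
    tremor_freq_mean: float = 8.0
    tremor_freq_sd: float = 1.0
    age_mean: float = 65.0
    age_sd: float = 8.0
    tetras_mean: float = 2.0
    tetras_sd: float = 1.5
    bdi_mean: float = 5.0
    bdi_sd: float = 4.0


@dataclass
class CohortEffects:
    """Effect structure for a two-group cohort (patients vs controls)."""

    pet: GroupEffects
    hc: GroupEffects

    @classmethod
    def default(cls) -> "CohortEffects":
        """Default study conditions: gain-dependent tremor increase in the
        patient group for all three modalities (strongest for combined
        audio-visual feedback), a smaller audio-visual-only effect in
        controls, and patient pupil dilation contrasts in the two
        auditory-involved conditions only."""
        pet = GroupEffects(
            tremor_amp0_median=0.03,
            tremor_amp0_sigma=0.25,
            gain_beta_median={"vo": 0.4, "va": 0.4, "ao": 0.4},
            gain_beta_sigma=0.25,
            pupil_delta_median={"vo": 0.0, "va": 0.25, "ao": 0.2},
            pupil_delta_sigma=0.3,
            tremor_freq_mean=6.0,
            tremor_freq_sd=1.0,
            age_mean=65.0,
            tetras_mean=25.0,
            tetras_sd=8.0,
            bdi_mean=8.0,
            bdi_sd=5.0,
        )
        hc = GroupEffects(
            tremor_amp0_median=0.012,
            tremor_amp0_sigma=0.25,
            gain_beta_median={"vo": 0.0, "va": 0.2, "ao": 0.0},
            gain_beta_sigma=0.25,
            pupil_delta_median={"vo": 0.0, "va": 0.0, "ao": 0.0},
            pupil_delta_sigma=0.3,
            tremor_freq_mean=9.0,
            tremor_freq_sd=1.5,
            age_mean=64.0,
            tetras_mean=2.0,
        )
        return cls(pet=pet, hc=hc)

    @classmethod
    def null(cls) -> "CohortEffects":
        """Zero-effect, fully exchangeable cohort for type-I calibration.

        All gain and pupil effects are zero and the participant-level
        spreads are degenerate, so trial outcomes are iid across the whole
        cohort -- the nominal null of every test in the stats layer,
        including the trial-level fixed-effects ANOVA.
        """
        g = GroupEffects(
            tremor_amp0_median=0.012,
            tremor_amp0_sigma=0.0,
            gain_beta_median={"vo": 0.0, "va": 0.0, "ao": 0.0},
            gain_beta_sigma=0.0,
            pupil_delta_median={"vo": 0.0, "va": 0.0, "ao": 0.0},
            pupil_delta_sigma=0.0,
            pupil_reactivity_sigma=0.0,
            tremor_freq_mean=8.0,
            tremor_freq_sd=0.0,
        )
        return cls(pet=g, hc=replace(g))

    def for_group(self, group: str) -> GroupEffects:
        return self.pet if group == "pET" else self.hc


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    if median == 0.0:
        return 0.0
    if sigma == 0.0:
        return median
    return float(median * np.exp(rng.normal(0.0, sigma)))


def draw_participant(
    pid: str, group: str, effects: GroupEffects, rng: np.random.Generator
) -> VirtualParticipant:
    """Draw one virtual participant from a group's parameter distributions."""
    beta_mult = np.exp(rng.normal(0.0, effects.gain_beta_sigma)) if effects.gain_beta_sigma else 1.0
    reactivity = (
        np.exp(rng.normal(0.0, effects.pupil_reactivity_sigma))
        if effects.pupil_reactivity_sigma
        else 1.0
    )
    delta_mult = (
        np.exp(rng.normal(0.0, effects.pupil_delta_sigma)) if effects.pupil_delta_sigma else 1.0
    )
    arousal: dict = {}
    for ftype in FEEDBACK_TYPES:
        low = effects.pupil_arousal_low_mm * reactivity
        arousal[(ftype, "low")] = low
        arousal[(ftype, "high")] = low + effects.pupil_delta_median[ftype] * delta_mult
    # tremor peaks are kept clear of the 4/12 Hz band edges by the Welch
    # mainlobe width, so band power captures the full oscillation
    freq = float(
        np.clip(rng.normal(effects.tremor_freq_mean, effects.tremor_freq_sd), 4.5, 11.5)
    )
    return VirtualParticipant(
        pid=pid,
        group=group,
        maxf=float(np.clip(rng.normal(60.0, 10.0), 20.0, None)),
        tremor_freq_hz=freq,
        tremor_amp0=_lognormal(rng, effects.tremor_amp0_median, effects.tremor_amp0_sigma),
        gain_beta={
            ftype: effects.gain_beta_median[ftype] * beta_mult for ftype in FEEDBACK_TYPES
        },
        pupil_base_mm=float(np.clip(rng.normal(4.0, 0.4), 2.0, 8.0)),
        pupil_arousal_mm=arousal,
        age=float(rng.normal(effects.age_mean, effects.age_sd)),
        tetras=float(np.clip(rng.normal(effects.tetras_mean, effects.tetras_sd), 0.0, None)),
        bdi=float(np.clip(rng.normal(effects.bdi_mean, effects.bdi_sd), 0.0, None)),
    )


# ---------------------------------------------------------------------------
# stream-level simulation
# ---------------------------------------------------------------------------

def _lowpass_noise(rng: np.random.Generator, n: int, cutoff_hz: float, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed at ``cutoff_hz``."""
    white = rng.standard_normal(n + 400)
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, white)[200:-200]
    sd = y.std()
    return y / sd if sd > 0 else y


def _tremor_amplitude(p: VirtualParticipant, trial: TrialSpec, weights: dict) -> float:
    boost = p.gain_beta[trial.feedback_type] * weights[trial.feedback_type]
    return p.tremor_amp0 * (1.0 + boost * (trial.gain_level == "high"))


def simulate_force_trial(
    p: VirtualParticipant,
    trial: TrialSpec,
    seed,
    fs: float = 80.0,
    feedback_weights: dict | None = None,
    ramp_in: bool = False,
) -> np.ndarray:
    """One trial's raw force segment (rest then task) at ``fs`` Hz.

    Task-window model, in raw force units with F_t the target force::

        F(t) = F_t * [1 + drift(t) + A sin(2 pi f_tremor t + phi) + eps(t)]

    where ``A = tremor_amp0 * (1 + gain_beta * weight * 1[gain=high])``,
    drift is low-passed Gaussian noise scaled to ``drift_amp`` and eps is
    white sensor noise.  The rest window is near-zero force with sensor
    noise; the last 0.5 s of rest ramps smoothly up to the target (and,
    with ``ramp_in``, the first 0.5 s ramps down from it) so the
    rest/task transition carries no broadband step.
    """
    weights = DEFAULT_FEEDBACK_WEIGHTS if feedback_weights is None else feedback_weights
    rng = np.random.default_rng(seed)
    n_rest = int(round(trial.rest_duration * fs))
    n_task = int(round(trial.task_duration * fs))
    f_t = p.f_t

    amp = _tremor_amplitude(p, trial, weights)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    t_task = np.arange(n_task) / fs
    task = np.ones(n_task)
    if p.drift_amp > 0:
        task = task + p.drift_amp * _lowpass_noise(rng, n_task, p.drift_cutoff_hz, fs)
    task = task + amp * np.sin(2.0 * np.pi * p.tremor_freq_hz * t_task + phi)
    if p.noise_sd > 0:
        task = task + p.noise_sd * rng.standard_normal(n_task)
    task = f_t * task

    rest = f_t * p.noise_sd * rng.standard_normal(n_rest) if p.noise_sd > 0 else np.zeros(n_rest)
    n_ramp = min(int(round(0.5 * fs)), n_rest)
    if n_ramp > 0:
        up = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        rest[n_rest - n_ramp:] = rest[n_rest - n_ramp:] + f_t * up
        if ramp_in:
            rest[:n_ramp] = rest[:n_ramp] + f_t * up[::-1]
    return np.clip(np.concatenate([rest, task]), 0.0, None)


def draw_gaze_wander(rng: np.random.Generator) -> list:
    """Amplitude/frequency/phase triples of the smooth fixation wander.

    One faster and one slow sinusoid per gaze axis; the faster component's
    acceleration amplitude is drawn in a fixed narrow range so clean gaze
    acceleration stays bounded well below the robust-z blink threshold.
    """
    out = []
    for _axis in range(2):
        comps = []
        f = rng.uniform(0.25, 0.40)
        accel_amp = rng.uniform(40.0, 60.0)  # px/s^2
        comps.append((min(accel_amp / (2.0 * np.pi * f) ** 2, 60.0), f,
                      rng.uniform(0.0, 2.0 * np.pi)))
        comps.append((rng.uniform(10.0, 30.0), rng.uniform(0.02, 0.08),
                      rng.uniform(0.0, 2.0 * np.pi)))
        out.append(comps)
    return out


def simulate_pupil_trial(
    p: VirtualParticipant,
    trial: TrialSpec,
    seed,
    fs: float = 240.0,
    gaze_wander: list | None = None,
    t_offset: float = 0.0,
):
    """One trial's pupil segment (rest then task) at ``fs`` Hz.

    Returns ``(frame, blink_intervals)`` where the frame has columns
    diameter_mm, confidence, gaze_x, gaze_y and blink_intervals are the
    ground-truth (start_s, end_s) dropouts relative to the segment start.

    Diameter follows ``base + arousal[type, gain] * ramp(task) + slow
    noise``; the dilation ramp rises linearly over the first
    ``PUPIL_RAMP_RISE_S`` seconds of the task and then plateaus.  Blinks
    are a Poisson process: the diameter collapses with 20 ms ramps, the
    confidence drops below 0.3 and the gaze trace carries an occlusion
    transient whose acceleration stands out at |z| > 3.  Clean gaze is a
    smooth fixation wander, so its acceleration is bounded well below the
    detection threshold.
    """
    rng = np.random.default_rng(seed)
    n_rest = int(round(trial.rest_duration * fs))
    n_task = int(round(trial.task_duration * fs))
    n = n_rest + n_task
    t = np.arange(n) / fs
    dur = n / fs

    ramp = np.zeros(n)
    t_task = t[n_rest:] - t[n_rest]
    ramp[n_rest:] = np.minimum(t_task / PUPIL_RAMP_RISE_S, 1.0)
    arousal = p.pupil_arousal_mm.get((trial.feedback_type, trial.gain_level), 0.0)
    diam = p.pupil_base_mm + arousal * ramp
    if p.pupil_noise_sd > 0:
        diam = diam + p.pupil_noise_sd * _lowpass_noise(rng, n, 0.5, fs)

    conf = np.clip(rng.normal(0.97, 0.015, n), 0.9, 1.0)

    # smooth fixation wander around screen centre plus occlusion pulses;
    # when called from simulate_session the wander parameters are shared
    # across trials and evaluated at the session clock, so the gaze trace
    # is continuous over trial boundaries
    if gaze_wander is None:
        gaze_wander = draw_gaze_wander(rng)
    gaze_x = np.full(n, 960.0)
    gaze_y = np.full(n, 540.0)
    t_abs = t + t_offset
    for target, comps in zip((gaze_x, gaze_y), gaze_wander):
        for a, f, ph in comps:
            target += a * np.sin(2.0 * np.pi * f * t_abs + ph)
    gaze_x += 1e-4 * rng.standard_normal(n)
    gaze_y += 1e-4 * rng.standard_normal(n)

    # blinks: Poisson count, starts kept apart by one blink duration
    intervals: list[tuple[float, float]] = []
    n_blinks = rng.poisson(p.blink_rate_hz * dur)
    starts = np.sort(rng.uniform(1.0, dur - 1.0 - p.blink_dur_s, size=n_blinks))
    last_end = -np.inf
    for s in starts:
        if s < last_end + p.blink_dur_s:
            continue
        e = s + p.blink_dur_s
        intervals.append((float(s), float(e)))
        last_end = e
        i0, i1 = int(round(s * fs)), int(round(e * fs))
        edge = max(int(round(0.02 * fs)), 1)  # 20 ms closure/opening ramps
        mult = np.full(i1 - i0, 0.05)
        mult[:edge] = np.linspace(1.0, 0.05, edge)
        mult[-edge:] = np.linspace(0.05, 1.0, edge)
        diam[i0:i1] = diam[i0:i1] * mult
        core0 = i0 + int(round(0.03 * fs))
        core1 = i1 - int(round(0.03 * fs))
        conf[core0:core1] = rng.uniform(0.02, 0.2, max(core1 - core0, 0))
        # occluded pupil centre jumps, giving sharp acceleration transients
        j0 = i0 + int(round(0.01 * fs))
        j1 = i1 - int(round(0.01 * fs))
        gaze_x[j0:j1] += 40.0
        gaze_y[j0:j1] -= 25.0

    frame = pd.DataFrame(
        {
            "diameter_mm": diam,
            "confidence": conf,
            "gaze_x": gaze_x,
            "gaze_y": gaze_y,
        }
    )
    return frame, intervals


def simulate_session(
    p: VirtualParticipant,
    seed,
    force_fs: float = 80.0,
    pupil_fs: float = 240.0,
    feedback_weights: dict | None = None,
    schedule: list | None = None,
) -> StreamSet:
    """Full 12-trial session for one participant: all three streams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sched_seed, gaze_seed, *trial_seeds = ss.spawn(2 + 12)
    if schedule is None:
        schedule = build_schedule(int(sched_seed.generate_state(1)[0] & 0x7FFFFFFF))
    wander = draw_gaze_wander(np.random.default_rng(gaze_seed))

    force_parts, pupil_parts, marker_rows, blink_truth = [], [], [], []
    t0 = 0.0
    for i, trial in enumerate(schedule):
        tseed = trial_seeds[i]
        f_seed, pu_seed = tseed.spawn(2)
        seg = simulate_force_trial(
            p, trial, f_seed, fs=force_fs, feedback_weights=feedback_weights, ramp_in=i > 0
        )
        pup, intervals = simulate_pupil_trial(
            p, trial, pu_seed, fs=pupil_fs, gaze_wander=wander, t_offset=t0
        )
        force_parts.append(seg)
        pupil_parts.append(pup)
        blink_truth.extend((t0 + a, t0 + b) for a, b in intervals)
        marker_rows += [
            (t0, "trial_start", trial.index, trial.feedback_type, trial.gain_level),
            (t0, "rest_onset", trial.index, trial.feedback_type, trial.gain_level),
            (t0 + trial.rest_duration, "task_onset", trial.index, trial.feedback_type, trial.gain_level),
            (t0 + trial.rest_duration + trial.task_duration, "task_offset", trial.index,
             trial.feedback_type, trial.gain_level),
        ]
        t0 += trial.rest_duration + trial.task_duration

    force = np.concatenate(force_parts)
    pupil = pd.concat(pupil_parts, ignore_index=True)
    force_df = pd.DataFrame(
        {"time_s": np.arange(force.size) / force_fs, "force": force}
    )
    pupil.insert(0, "time_s", np.arange(len(pupil)) / pupil_fs)
    markers = pd.DataFrame(
        marker_rows, columns=["time_s", "label", "trial_index", "feedback_type", "gain_level"]
    )
    out = StreamSet(
        force=force_df, pupil=pupil, markers=markers,
        schedule=schedule, blink_truth=blink_truth,
    )
    out.validate()
    return out


def simulate_cohort(
    n_per_group: int,
    effects: CohortEffects | None = None,
    seed=0,
    force_fs: float = 80.0,
    pupil_fs: float = 240.0,
    feedback_weights: dict | None = None,
) -> list[tuple[VirtualParticipant, StreamSet]]:
    """Simulate a full two-group cohort of stream recordings."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    effects = CohortEffects.default() if effects is None else effects
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = []
    children = ss.spawn(2 * n_per_group)
    k = 0
    for group, n in (("pET", n_per_group), ("HC", n_per_group)):
        for j in range(n):
            child = children[k]
            k += 1
            p_seed, s_seed = child.spawn(2)
            rng = np.random.default_rng(p_seed)
            p = draw_participant(f"{group}{j + 1:02d}", group, effects.for_group(group), rng)
            streams = simulate_session(
                p, s_seed, force_fs=force_fs, pupil_fs=pupil_fs,
                feedback_weights=feedback_weights,
            )
            out.append((p, streams))
    return out


# ---------------------------------------------------------------------------
# feature-level simulation (same model, no waveforms)
# ---------------------------------------------------------------------------

def _measured_trial_features(
    p: VirtualParticipant,
    trial: TrialSpec,
    rng: np.random.Generator,
    weights: dict,
    task_duration_s: float = 30.0,
) -> dict:
    """Draw one trial's measured features from the model's sampling
    distribution: analytic sinusoid band power plus the white-noise band
    floor with Welch estimation scatter, realised drift power, and the
    slow-noise scatter of the baseline-corrected pupil mean."""
    amp = _tremor_amplitude(p, trial, weights)
    sin_power = 0.5 * amp**2
    # white noise spreads its variance over the 0-40 Hz Nyquist range;
    # the 4-12 Hz tremor band holds 8/40 of it
    floor = p.noise_sd**2 * 8.0 / 40.0
    tremor_power = max(
        sin_power * (1.0 + 0.03 * rng.standard_normal())
        + floor * (1.0 + 0.10 * rng.standard_normal()),
        0.0,
    )
    drift_power = p.drift_amp**2 * max(
        1.0 + DRIFT_POWER_REL_SD * rng.standard_normal(), 0.05
    )
    voluntary_power = 0.9 * drift_power  # 0.1 Hz high-pass sheds a little
    mean_force = 1.0 + 0.15 * p.drift_amp * rng.standard_normal()
    rmse = float(
        np.sqrt(drift_power + p.noise_sd**2 + sin_power + (mean_force - 1.0) ** 2)
    )
    arousal = p.pupil_arousal_mm.get((trial.feedback_type, trial.gain_level), 0.0)
    pupil_mean = arousal * pupil_ramp_mean(task_duration_s) + PUPIL_TRIAL_MEAN_SD * (
        rng.standard_normal()
    )
    return {
        "trial_index": trial.index,
        "feedback_type": trial.feedback_type,
        "gain_level": trial.gain_level,
        "tremor_power": tremor_power,
        "voluntary_power": voluntary_power,
        "mean_force": mean_force,
        "rmse": rmse,
        "pupil_mean": pupil_mean,
    }


def simulate_trial_features(
    n_per_group: int,
    effects: CohortEffects | None = None,
    seed=0,
    feedback_weights: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort's tidy feature table without rendering waveforms.

    Returns ``(participants, features)`` frames matching the output of the
    full stream pipeline; used for calibration experiments that need
    hundreds to thousands of cohorts.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2")
    effects = CohortEffects.default() if effects is None else effects
    weights = DEFAULT_FEEDBACK_WEIGHTS if feedback_weights is None else feedback_weights
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    rows, people = [], []
    k = 0
    for group, n in (("pET", n_per_group), ("HC", n_per_group)):
        for j in range(n):
            child = children[k]
            k += 1
            p_seed, t_seed = child.spawn(2)
            rng = np.random.default_rng(p_seed)
            p = draw_participant(f"{group}{j + 1:02d}", group, effects.for_group(group), rng)
            people.append(p)
            trng = np.random.default_rng(t_seed)
            sched = build_schedule(int(t_seed.generate_state(1)[0] & 0x7FFFFFFF))
            for trial in sched:
                row = _measured_trial_features(p, trial, trng, weights)
                row["pid"] = p.pid
                row["group"] = p.group
                rows.append(row)
    features = pd.DataFrame(rows)[
        ["pid", "group", "trial_index", "feedback_type", "gain_level",
         "tremor_power", "voluntary_power", "mean_force", "rmse", "pupil_mean"]
    ]
    return participants_frame(people), features


def participants_frame(people: list[VirtualParticipant]) -> pd.DataFrame:
    """Covariate table (one row per participant) for the stats layer."""
    return pd.DataFrame(
        {
            "pid": [p.pid for p in people],
            "group": [p.group for p in people],
            "maxf": [p.maxf for p in people],
            "age": [p.age for p in people],
            "tetras": [p.tetras for p in people],
            "bdi": [p.bdi for p in people],
        }
    )
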