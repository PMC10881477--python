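"""Force processing chain: normalisation, band-pass filtering, epoching,
Welch spectra and per-trial scalar features.

Every sample is first divided by 15% of the participant's maximum force,
so a perfectly matched target reads exactly 1.0 and all downstream
quantities are in normalized force units.  The continuous normalized
stream is band-passed 0.1-12 Hz (5th-order Butterworth in second-order
sections, applied forward-backward for zero phase), cut into 30 s task
epochs at the event markers, and each epoch's power spectral density is
estimated by Welch's method.  Tremor severity is the integrated PSD over
4-12 Hz; voluntary (non-tremulous corrective) movement is the 0-3 Hz
integral.  Mean force and the RMSE to the target are computed on the
*unfiltered* normalized task epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import RunConfig
from .protocol import TrialSpec

__all__ = [
    "Spectrum",
    "TrialEpoch",
    "EpochTooShortError",
    "MarkerError",
    "normalize_force",
    "bandpass_force",
    "epoch_stream",
    "welch_psd",
    "band_power",
    "trial_error_stats",
    "extract_force_features",
]


class EpochTooShortError(ValueError):
    """Trace too short for the requested filter or spectral window."""


class MarkerError(ValueError):
    """Malformed or unmatched event markers."""


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density on a regular frequency grid."""

    freqs_hz: np.ndarray
    psd: np.ndarray  # (normalized force)^2 / Hz

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz)
        if f.size and (np.any(np.diff(f) <= 0) or f[0] < 0):
            raise ValueError("frequency grid must be non-negative and increasing")
        if np.any(np.asarray(self.psd) < -1e-30):
            raise ValueError("psd must be non-negative")


@dataclass
class TrialEpoch:
    """One trial's extracted signal windows (filtered and raw)."""

    trial: TrialSpec
    task: np.ndarray
    rest: np.ndarray
    task_raw: np.ndarray  # unfiltered normalized samples, for MF / RMSE
    rest_raw: np.ndarray


def normalize_force(trace, maxf: float) -> np.ndarray:
    """Divide every sample by MaxF * 0.15 so the target reads 1.0."""
    if not maxf > 0:
        raise ValueError(f"MaxF must be positive, got {maxf}")
    return np.asarray(trace, dtype=float) / (0.15 * maxf)


def design_bandpass(fs: float, low_hz: float = 0.1, high_hz: float = 12.0, order: int = 5):
    """SOS coefficients of the analysis band-pass filter."""
    if fs <= 2 * high_hz:
        raise ValueError("passband must fit below Nyquist")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_force(
    trace, fs: float = 80.0, low_hz: float = 0.1, high_hz: float = 12.0, order: int = 5
) -> np.ndarray:
    """Zero-phase 5th-order Butterworth band-pass, 0.1-12 Hz, via SOS.

    Applied forward-backward (``sosfiltfilt``), so the effective
    attenuation is twice the single-pass magnitude response and the output
    has no phase distortion.  Output length equals input length.
    """
    x = np.asarray(trace, dtype=float)
    sos = design_bandpass(fs, low_hz, high_hz, order)
    # sosfiltfilt pads with edge reflections; demand a comfortable margin
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= 3 * padlen:
        raise EpochTooShortError(
            f"trace of {x.size} samples is too short to filter (need > {3 * padlen})"
        )
    return signal.sosfiltfilt(sos, x)


def epoch_stream(trace, timestamps, markers: pd.DataFrame) -> list[TrialEpoch]:
    """Cut a (filtered) stream into per-trial task and rest epochs.

    ``markers`` must hold matched rest_onset / task_onset / task_offset
    rows per trial; windows are half-open ``[onset, offset)`` on the
    timestamps.  An optional second array-like can be carried through via
    ``trace`` being 2-row (filtered, raw); see ``extract_force_features``.
    """
    trace = np.atleast_2d(np.asarray(trace, dtype=float))
    timestamps = np.asarray(timestamps, dtype=float)
    markers = markers.sort_values(["trial_index", "time_s"], kind="stable")
    epochs: list[TrialEpoch] = []
    for idx, grp in markers.groupby("trial_index", sort=True):
        times = {row.label: row.time_s for row in grp.itertuples()}
        for needed in ("rest_onset", "task_onset", "task_offset"):
            if needed not in times:
                raise MarkerError(f"trial {idx}: missing {needed} marker")
        if not times["rest_onset"] <= times["task_onset"] < times["task_offset"]:
            raise MarkerError(f"trial {idx}: marker times out of order")
        spec = TrialSpec(
            index=int(idx),
            feedback_type=str(grp["feedback_type"].iloc[0]),
            gain_level=str(grp["gain_level"].iloc[0]),
            rest_duration=float(times["task_onset"] - times["rest_onset"]),
            task_duration=float(times["task_offset"] - times["task_onset"]),
        )
        r0, r1 = np.searchsorted(timestamps, [times["rest_onset"], times["task_onset"]])
        t0, t1 = np.searchsorted(timestamps, [times["task_onset"], times["task_offset"]])
        filt = trace[0]
        raw = trace[1] if trace.shape[0] > 1 else trace[0]
        epochs.append(
            TrialEpoch(
                trial=spec,
                task=filt[t0:t1],
                rest=filt[r0:r1],
                task_raw=raw[t0:t1],
                rest_raw=raw[r0:r1],
            )
        )
    return epochs


def welch_psd(
    epoch,
    fs: float,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> Spectrum:
    """Welch average periodogram: 4 s Hann segments, 50% overlap, density
    scaling.  The 4 s window gives 0.25 Hz resolution, putting the 3 Hz
    and 4 Hz band edges exactly on the frequency grid."""
    x = np.asarray(epoch, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise EpochTooShortError(
            f"epoch of {x.size} samples is shorter than one {nperseg}-sample window"
        )
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    return Spectrum(freqs_hz=freqs, psd=psd)


def band_power(spec: Spectrum, lo_hz: float, hi_hz: float) -> float:
    """Trapezoidal integral of the PSD over ``[lo_hz, hi_hz]`` (units: power)."""
    if lo_hz > hi_hz:
        raise ValueError("band low edge must not exceed the high edge")
    f = np.asarray(spec.freqs_hz)
    if lo_hz < f[0] - 1e-9 or hi_hz > f[-1] + 1e-9:
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}] Hz lies outside the spectral grid "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    if lo_hz == hi_hz:
        return 0.0
    mask = (f >= lo_hz - 1e-9) & (f <= hi_hz + 1e-9)
    return float(np.trapezoid(np.asarray(spec.psd)[mask], f[mask]))


def trial_error_stats(raw_task_epoch) -> tuple[float, float]:
    """Mean force and RMSE to the normalized target (1.0), unfiltered."""
    x = np.asarray(raw_task_epoch, dtype=float)
    if x.size == 0:
        raise ValueError("empty epoch")
    return float(np.mean(x)), float(np.sqrt(np.mean((x - 1.0) ** 2)))


def extract_force_features(
    force: pd.DataFrame,
    markers: pd.DataFrame,
    maxf: float,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Full chain for one session: normalize -> filter the continuous
    stream -> epoch -> Welch -> band powers, plus unfiltered MF / RMSE.

    Returns one row per trial with columns trial_index, feedback_type,
    gain_level, tremor_power, voluntary_power, mean_force, rmse.
    """
    cfg = RunConfig() if cfg is None else cfg
    t = force["time_s"].to_numpy()
    normalized = normalize_force(force["force"].to_numpy(), maxf)
    filtered = bandpass_force(
        normalized, fs=cfg.force_fs_hz, low_hz=cfg.filter_low_hz,
        high_hz=cfg.filter_high_hz, order=cfg.filter_order,
    )
    epochs = epoch_stream(np.vstack([filtered, normalized]), t, markers)
    rows = []
    for ep in epochs:
        spec = welch_psd(
            ep.task, fs=cfg.force_fs_hz, window_s=cfg.welch_window_s,
            overlap=cfg.welch_overlap,
        )
        mf, rmse = trial_error_stats(ep.task_raw)
        rows.append(
            {
                "trial_index": ep.trial.index,
                "feedback_type": ep.trial.feedback_type,
                "gain_level": ep.trial.gain_level,
                "tremor_power": band_power(spec, cfg.tremor_band_lo_hz, cfg.tremor_band_hi_hz),
                "voluntary_power": band_power(
                    spec, cfg.voluntary_band_lo_hz, cfg.voluntary_band_hi_hz
                ),
                "mean_force": mf,
                "rmse": rmse,
            }
        )
    return pd.DataFrame(rows)
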