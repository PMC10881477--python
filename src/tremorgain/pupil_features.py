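"""Pupillometry chain: blink detection, gap interpolation, epoching,
per-epoch subtractive baseline correction and the task-window mean.

Blinks are detected from two vendor-style quality signals -- the
per-sample confidence score and anomalies in gaze acceleration -- marked
as NaN, and filled by a normalized Gaussian FFT convolution (missing
samples excluded from the weight normalisation, valid samples returned
untouched).  Each trial epoch is baseline-corrected by subtracting the
mean of the -10..-2 s pre-task window (the tail of the 30 s rest period)
and summarised by its mean over the 30 s task window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import RunConfig

__all__ = [
    "BlinkMask",
    "PupilQualityError",
    "detect_blinks",
    "interpolate_gaps",
    "gaussian_kernel",
    "baseline_correct_epoch",
    "pupil_trial_mean",
    "extract_pupil_features",
]


class PupilQualityError(ValueError):
    """Epoch or recording unusable for pupillometry."""


@dataclass
class BlinkMask:
    """Per-sample blink validity plus the merged, padded intervals."""

    mask: np.ndarray  # True where a sample is blink-contaminated
    intervals: list = field(default_factory=list)  # (start_s, end_s)

    @property
    def nan_fraction(self) -> float:
        return float(np.mean(self.mask)) if self.mask.size else 0.0


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_blinks(
    pupil: pd.DataFrame,
    fs: float,
    conf_threshold: float = 0.6,
    accel_z_threshold: float = 3.0,
    pad_s: float = 0.1,
) -> BlinkMask:
    """Flag blink-contaminated samples.

    A sample is flagged when its confidence falls below ``conf_threshold``
    OR the robust z-score (median/MAD) of its gaze-acceleration magnitude
    exceeds ``accel_z_threshold``.  Flagged runs closer than ``2 * pad_s``
    are merged and every run is padded by ``pad_s`` on each side.
    """
    for col in ("confidence", "gaze_x", "gaze_y"):
        if col not in pupil.columns:
            raise PupilQualityError(f"pupil stream is missing column {col!r}")
    conf = pupil["confidence"].to_numpy(dtype=float)
    n = conf.size
    dt = 1.0 / fs
    ax = np.gradient(np.gradient(pupil["gaze_x"].to_numpy(dtype=float), dt), dt)
    ay = np.gradient(np.gradient(pupil["gaze_y"].to_numpy(dtype=float), dt), dt)
    accel = np.hypot(ax, ay)
    med = np.median(accel)
    mad = np.median(np.abs(accel - med))
    scale = 1.4826 * mad
    if scale > 0:
        z = (accel - med) / scale
    else:
        z = np.where(accel == med, 0.0, np.inf)
    flagged = (conf < conf_threshold) | (z > accel_z_threshold)

    pad = int(round(pad_s * fs))
    runs = _runs(flagged)
    # merge runs separated by less than two pads, then pad
    merged: list[list[int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] < 2 * pad:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    mask = np.zeros(n, dtype=bool)
    intervals = []
    for a, b in merged:
        a, b = max(a - pad, 0), min(b + pad, n)
        mask[a:b] = True
        intervals.append((a / fs, b / fs))
    return BlinkMask(mask=mask, intervals=intervals)


def gaussian_kernel(span_samples: int = 120) -> np.ndarray:
    """Normalised Gaussian kernel with total support ~= ``span_samples``.

    The span is read as the kernel's support: standard deviation
    span/8 samples, so the +-4 sigma tails fit inside the span.  At the
    240 Hz pupil rate the default 120-sample span covers 0.5 s.
    """
    sigma = span_samples / 8.0
    k = signal.windows.gaussian(span_samples + 1, std=sigma)
    return k / k.sum()


def interpolate_gaps(
    trace,
    kernel_span_samples: int = 120,
    max_nan_fraction: float = 0.5,
    max_passes: int = 25,
    refine_iters: int = 10,
) -> np.ndarray:
    """Replace NaN samples by Gaussian-weighted FFT convolution of their
    valid neighbours.

    The convolution is normalized by the convolved validity mask, so
    missing samples carry no weight; valid samples are returned exactly
    unchanged.  Gaps wider than the kernel support are filled iteratively
    from their edges inward.  A few fixed-point refinement passes then
    re-smooth the filled positions (only those) against their full
    neighbourhood, removing the one-sided centroid bias a single
    normalized pass leaves on sloped signals.
    """
    x = np.asarray(trace, dtype=float).copy()
    invalid0 = np.isnan(x)
    nan_frac = float(np.mean(invalid0))
    if nan_frac >= max_nan_fraction:
        raise PupilQualityError(
            f"{nan_frac:.0%} of samples are missing (limit {max_nan_fraction:.0%})"
        )
    if not invalid0.any():
        return x
    kernel = gaussian_kernel(kernel_span_samples)
    for _ in range(max_passes):
        invalid = np.isnan(x)
        if not invalid.any():
            break
        valid = ~invalid
        num = signal.fftconvolve(np.where(valid, x, 0.0), kernel, mode="same")
        den = signal.fftconvolve(valid.astype(float), kernel, mode="same")
        fillable = invalid & (den > 1e-10)
        if not fillable.any():
            break
        x[fillable] = num[fillable] / den[fillable]
    if np.isnan(x).any():
        raise PupilQualityError("gaps too wide to interpolate")
    edge = signal.fftconvolve(np.ones_like(x), kernel, mode="same")
    for _ in range(refine_iters):
        sm = signal.fftconvolve(x, kernel, mode="same") / edge
        x[invalid0] = sm[invalid0]
    return x


def baseline_correct_epoch(
    times_rel,
    values,
    baseline_window: tuple[float, float] = (-10.0, -2.0),
) -> np.ndarray:
    """Subtract the mean of the pre-task baseline window from every sample.

    ``times_rel`` are seconds relative to task onset; the baseline window
    is half-open ``[start, end)`` and must be fully covered by the epoch.
    """
    t = np.asarray(times_rel, dtype=float)
    x = np.asarray(values, dtype=float)
    lo, hi = baseline_window
    dt = np.median(np.diff(t)) if t.size > 1 else 0.0
    if t.size == 0 or t[0] > lo + dt + 1e-9 or t[-1] < hi - dt - 1e-9:
        raise PupilQualityError(
            f"epoch [{t[0] if t.size else np.nan:.2f}, {t[-1] if t.size else np.nan:.2f}] s "
            f"does not cover the baseline window [{lo}, {hi}) s"
        )
    sel = (t >= lo) & (t < hi)
    base = x[sel]
    if base.size == 0 or np.all(np.isnan(base)):
        raise PupilQualityError("baseline window has no usable samples")
    return x - np.nanmean(base)


def pupil_trial_mean(times_rel, corrected, task_window: tuple[float, float] = (0.0, 30.0)) -> float:
    """Mean baseline-corrected diameter over the (half-open) task window."""
    t = np.asarray(times_rel, dtype=float)
    x = np.asarray(corrected, dtype=float)
    sel = (t >= task_window[0]) & (t < task_window[1])
    if not sel.any():
        raise PupilQualityError("epoch has no samples in the task window")
    return float(np.mean(x[sel]))


def extract_pupil_features(
    pupil: pd.DataFrame,
    markers: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full chain for one session.

    Blink detection and interpolation run on the continuous recording;
    epochs of ``[-rest, +task)`` s around each task onset are then
    baseline-corrected individually and averaged over the task window.

    Returns ``(features, quality)``: per-trial pupil means (NaN where the
    epoch was rejected) and a quality report with the per-epoch NaN
    fraction, blink count and rejection reason.
    """
    cfg = RunConfig() if cfg is None else cfg
    fs = cfg.pupil_fs_hz
    t = pupil["time_s"].to_numpy(dtype=float)
    blinks = detect_blinks(
        pupil, fs=fs, conf_threshold=cfg.conf_threshold,
        accel_z_threshold=cfg.accel_z_threshold, pad_s=cfg.blink_pad_s,
    )
    diam = pupil["diameter_mm"].to_numpy(dtype=float).copy()
    diam[blinks.mask] = np.nan

    feature_rows, quality_rows = [], []
    onsets = markers[markers["label"] == "task_onset"].sort_values("trial_index")
    for row in onsets.itertuples():
        onset = float(row.time_s)
        lo = onset - cfg.rest_duration_s
        hi = onset + cfg.task_duration_s
        sel = (t >= lo) & (t < hi)
        t_rel = t[sel] - onset
        seg = diam[sel]
        nan_frac = float(np.mean(np.isnan(seg))) if seg.size else 1.0
        n_blinks = sum(1 for a, b in blinks.intervals if a < hi and b > lo)
        mean_mm, reason = np.nan, ""
        try:
            filled = interpolate_gaps(
                seg, kernel_span_samples=cfg.kernel_span_samples,
                max_nan_fraction=cfg.max_nan_fraction,
            )
            corrected = baseline_correct_epoch(
                t_rel, filled, (cfg.baseline_start_s, cfg.baseline_end_s)
            )
            mean_mm = pupil_trial_mean(t_rel, corrected, (0.0, cfg.task_duration_s))
        except PupilQualityError as err:
            reason = str(err)
        feature_rows.append(
            {
                "trial_index": int(row.trial_index),
                "feedback_type": row.feedback_type,
                "gain_level": row.gain_level,
                "pupil_mean": mean_mm,
            }
        )
        quality_rows.append(
            {
                "trial_index": int(row.trial_index),
                "nan_fraction": nan_frac,
                "n_blinks": n_blinks,
                "rejected": bool(reason),
                "reason": reason,
            }
        )
    return pd.DataFrame(feature_rows), pd.DataFrame(quality_rows)
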