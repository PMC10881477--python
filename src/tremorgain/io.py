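"""Session file formats and the end-to-end pipeline runner.

A session directory holds three delimited text tables sharing one clock:

* ``force.tsv`` -- time_s, force (80 Hz, arbitrary force units)
* ``pupil.tsv`` -- time_s, diameter_mm, confidence, gaze_x, gaze_y (240 Hz)
* ``markers.tsv`` -- time_s, label, trial_index, feedback_type, gain_level

A cohort directory adds ``participants.tsv`` (pid, group, maxf and
clinical covariates) and ``manifest.tsv`` listing the session
subdirectories.  ``run_pipeline`` ties simulation, feature extraction and
statistics into one deterministic run whose output directory carries its
own config copy and log.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .force_features import extract_force_features
from .pupil_features import extract_pupil_features
from .stats import run_full_stats
from .synth import CohortEffects, StreamSet, participants_frame, simulate_cohort

__all__ = [
    "StreamFormatError",
    "write_session",
    "read_streams",
    "write_cohort",
    "extract_session_features",
    "run_pipeline",
]

_FLOAT_FMT = "%.10g"

_REQUIRED = {
    "force.tsv": ["time_s", "force"],
    "pupil.tsv": ["time_s", "diameter_mm", "confidence", "gaze_x", "gaze_y"],
    "markers.tsv": ["time_s", "label", "trial_index", "feedback_type", "gain_level"],
}


class StreamFormatError(ValueError):
    """Missing file or column, or malformed timestamps, in a session."""


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_session(streams: StreamSet, directory) -> Path:
    """Write one session's three stream tables."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_tsv(streams.force, d / "force.tsv")
    _write_tsv(streams.pupil, d / "pupil.tsv")
    _write_tsv(streams.markers, d / "markers.tsv")
    return d


def read_streams(session_dir, cfg: RunConfig | None = None) -> StreamSet:
    """Load and validate one session directory.

    Markers are sorted on load, so row order on disk is immaterial.
    Sampling rates deviating more than 1% from the configured rates raise
    a warning.
    """
    cfg = RunConfig() if cfg is None else cfg
    d = Path(session_dir)
    frames = {}
    for fname, cols in _REQUIRED.items():
        path = d / fname
        if not path.exists():
            raise StreamFormatError(f"missing stream file {fname} in {d}")
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise StreamFormatError(f"{fname}: missing columns {missing}")
        df["time_s"] = df["time_s"].astype(float)
        frames[fname] = df
    markers = frames["markers.tsv"].sort_values(
        ["time_s", "trial_index"], kind="stable"
    ).reset_index(drop=True)
    for fname, nominal in (("force.tsv", cfg.force_fs_hz), ("pupil.tsv", cfg.pupil_fs_hz)):
        t = frames[fname]["time_s"].to_numpy(dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise StreamFormatError(f"{fname}: timestamps not strictly increasing")
        fs = 1.0 / np.median(np.diff(t))
        if abs(fs - nominal) / nominal > 0.01:
            warnings.warn(
                f"{fname}: observed rate {fs:.2f} Hz deviates >1% from "
                f"configured {nominal:g} Hz",
                stacklevel=2,
            )
    out = StreamSet(
        force=frames["force.tsv"], pupil=frames["pupil.tsv"], markers=markers
    )
    out.validate()
    return out


def write_cohort(cohort, directory) -> Path:
    """Write a simulated cohort: session subdirectories plus the
    participant covariate table and a manifest of sessions."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    people = []
    rows = []
    for p, streams in cohort:
        write_session(streams, d / "sessions" / p.pid)
        people.append(p)
        rows.append({"pid": p.pid, "session": f"sessions/{p.pid}"})
    _write_tsv(participants_frame(people), d / "participants.tsv")
    _write_tsv(pd.DataFrame(rows), d / "manifest.tsv")
    return d


def extract_session_features(
    streams: StreamSet, maxf: float, cfg: RunConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Force and pupil features for one session, merged per trial."""
    cfg = RunConfig() if cfg is None else cfg
    force_feats = extract_force_features(streams.force, streams.markers, maxf, cfg)
    pupil_feats, quality = extract_pupil_features(streams.pupil, streams.markers, cfg)
    merged = force_feats.merge(
        pupil_feats, on=["trial_index", "feedback_type", "gain_level"], how="left"
    )
    return merged, quality


def run_pipeline(
    cfg: RunConfig,
    out_dir,
    data_dir=None,
    effects: CohortEffects | None = None,
) -> Path:
    """One reproducible run: simulate (or load), extract, test, report.

    Writes features.tsv, results.tsv, report.txt, quality.tsv, log.txt
    and a verbatim config copy into ``out_dir``.  Deterministic given the
    config's master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config: master_seed={cfg.master_seed} n_per_group={cfg.n_per_group}"]

    if cfg.simulate:
        if effects is None:
            effects = (
                CohortEffects.null() if getattr(cfg, "effects_preset", "default") == "null"
                else CohortEffects.default()
            )
        cohort = simulate_cohort(
            cfg.n_per_group, effects, seed=cfg.master_seed,
            force_fs=cfg.force_fs_hz, pupil_fs=cfg.pupil_fs_hz,
            feedback_weights=cfg.feedback_weights,
        )
        sessions = [(p.pid, p.maxf, streams) for p, streams in cohort]
        participants = participants_frame([p for p, _ in cohort])
        log.append(f"simulated {len(sessions)} sessions")
    else:
        if data_dir is None:
            raise ValueError("data_dir required when simulate is false")
        data = Path(data_dir)
        participants = pd.read_csv(data / "participants.tsv", sep="\t")
        manifest = pd.read_csv(data / "manifest.tsv", sep="\t")
        sessions = []
        for row in manifest.itertuples():
            streams = read_streams(data / row.session, cfg)
            maxf = float(
                participants.loc[participants["pid"] == row.pid, "maxf"].iloc[0]
            )
            sessions.append((row.pid, maxf, streams))
        log.append(f"loaded {len(sessions)} sessions from {data}")

    group_of = dict(zip(participants["pid"], participants["group"]))
    feat_parts, quality_parts = [], []
    for pid, maxf, streams in sessions:
        feats, quality = extract_session_features(streams, maxf, cfg)
        feats.insert(0, "pid", pid)
        feats.insert(1, "group", group_of[pid])
        quality.insert(0, "pid", pid)
        feat_parts.append(feats)
        quality_parts.append(quality)
    features = pd.concat(feat_parts, ignore_index=True)
    quality = pd.concat(quality_parts, ignore_index=True)
    log.append(f"extracted features: {len(features)} trials, "
               f"{int(quality['rejected'].sum())} pupil epochs rejected")

    results, report = run_full_stats(
        features, participants, alpha=cfg.alpha,
        contrast_unit=cfg.contrast_unit, holm_correction=cfg.holm_correction,
    )
    log.append(f"statistics: {len(results)} tests at alpha={cfg.alpha}, "
               f"unit={cfg.contrast_unit}")

    _write_tsv(features, out / "features.tsv")
    _write_tsv(quality, out / "quality.tsv")
    _write_tsv(results, out / "results.tsv")
    _write_tsv(participants, out / "participants.tsv")
    (out / "report.txt").write_text(report)
    cfg.to_file(out / "config.yaml")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out
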