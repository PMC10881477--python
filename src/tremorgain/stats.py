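"""Statistical layer over the tidy per-trial feature table.

The primary outcome is the within-participant high-minus-low feedback
contrast of tremor band power, computed per feedback modality and
compared between patients and controls with two-sample t-tests; the same
contrast logic applies to the baseline-corrected pupil mean.  Within-group
gain effects use paired tests with a normality-gated Wilcoxon fallback.
Trial-level control outcomes (RMSE, mean force, voluntary power) get
fixed-effects one-way ANOVAs per factor.  Clinical covariates are
compared with a Shapiro-Wilk-gated Mann-Whitney U, and correlations use a
Shapiro/Levene-gated Pearson-vs-Spearman choice with an optional partial
covariate.  Every gated test records which branch ran.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .protocol import FEEDBACK_TYPES
from .synth import CohortEffects, simulate_trial_features

__all__ = [
    "TestResult",
    "build_contrasts",
    "group_ttest",
    "paired_gain_test",
    "anova_trials",
    "compare_covariates",
    "correlate",
    "sequential_power",
    "SequentialPowerResult",
    "run_full_stats",
]


@dataclass
class TestResult:
    """One test's outcome in the shape results are reported: statistic
    name and value, degrees of freedom, p-value, cells compared."""

    name: str
    statistic: str  # "t", "U", "F", "W", "r", "rho"
    value: float
    p_value: float
    df: tuple | float | None = None
    n: tuple | int | None = None
    comparison: str = ""
    branch: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_row(self) -> dict:
        df = self.df if isinstance(self.df, tuple) else (self.df, None)
        n = self.n if isinstance(self.n, tuple) else (self.n, None)
        return {
            "test": self.name,
            "comparison": self.comparison,
            "statistic": self.statistic,
            "value": self.value,
            "df1": df[0],
            "df2": df[1],
            "p_value": self.p_value,
            "n1": n[0],
            "n2": n[1],
            "branch": self.branch,
        }

    def __str__(self) -> str:
        df = self.df
        if isinstance(df, tuple):
            dftxt = ", ".join("" if d is None else f"{d:g}" for d in df if d is not None)
        else:
            dftxt = "" if df is None else f"{df:g}"
        tag = f"{self.statistic}[{dftxt}]" if dftxt else self.statistic
        branch = f" ({self.branch})" if self.branch else ""
        return f"{self.comparison}: {tag} = {self.value:.3f}, p = {self.p_value:.4g}{branch}"


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def build_contrasts(features: pd.DataFrame, unit: str = "trial_pair") -> pd.DataFrame:
    """High-minus-low feedback contrasts per participant and modality.

    ``unit='trial_pair'`` pairs the k-th low-gain with the k-th high-gain
    trial (in presentation order) within each (participant, modality)
    cell, yielding two delta rows per cell; ``unit='participant'``
    averages the two trials per gain level first, yielding one row.
    Cells missing a gain level are dropped.
    """
    if unit not in ("trial_pair", "participant"):
        raise ValueError(f"unknown contrast unit {unit!r}")
    rows = []
    for (pid, group, ftype), cell in features.groupby(
        ["pid", "group", "feedback_type"], sort=True
    ):
        low = cell[cell["gain_level"] == "low"].sort_values("trial_index")
        high = cell[cell["gain_level"] == "high"].sort_values("trial_index")
        if low.empty or high.empty:
            continue
        if unit == "trial_pair":
            for k in range(min(len(low), len(high))):
                rows.append(
                    {
                        "pid": pid,
                        "group": group,
                        "feedback_type": ftype,
                        "pair_index": k + 1,
                        "delta_tremor_power": high["tremor_power"].iloc[k]
                        - low["tremor_power"].iloc[k],
                        "delta_pupil_mean": high["pupil_mean"].iloc[k]
                        - low["pupil_mean"].iloc[k],
                    }
                )
        else:
            rows.append(
                {
                    "pid": pid,
                    "group": group,
                    "feedback_type": ftype,
                    "pair_index": 1,
                    "delta_tremor_power": high["tremor_power"].mean()
                    - low["tremor_power"].mean(),
                    "delta_pupil_mean": high["pupil_mean"].mean()
                    - low["pupil_mean"].mean(),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pid", "group", "feedback_type", "pair_index",
            "delta_tremor_power", "delta_pupil_mean",
        ],
    )


def group_ttest(
    contrasts: pd.DataFrame,
    feedback_type: str,
    outcome: str = "delta_tremor_power",
) -> TestResult:
    """Two-sample t-test of patient vs control contrasts for one modality."""
    sub = contrasts[contrasts["feedback_type"] == feedback_type].dropna(subset=[outcome])
    a = sub.loc[sub["group"] == "pET", outcome].to_numpy()
    b = sub.loc[sub["group"] == "HC", outcome].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need >= 2 contrasts per group for {feedback_type}")
    res = sps.ttest_ind(a, b, equal_var=True)
    branch = ""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        branch = "degenerate: zero variance in both groups"
    return TestResult(
        name="group_ttest",
        statistic="t",
        value=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(a.size + b.size - 2),
        n=(int(a.size), int(b.size)),
        comparison=f"pET vs HC, {outcome} ({feedback_type})",
        branch=branch,
    )


def paired_gain_test(
    features: pd.DataFrame,
    group: str,
    feedback_type: str,
    outcome: str = "tremor_power",
    alpha: float = 0.05,
) -> TestResult:
    """Within-group high-vs-low gain test on participant means.

    Paired t-test by default; when a Shapiro-Wilk test rejects normality
    of the paired differences at ``alpha``, a Wilcoxon signed-rank test is
    used instead.  The branch taken is recorded.
    """
    sub = features[
        (features["group"] == group) & (features["feedback_type"] == feedback_type)
    ]
    means = sub.groupby(["pid", "gain_level"])[outcome].mean().unstack("gain_level")
    means = means.dropna()
    if len(means) < 3 or "low" not in means or "high" not in means:
        raise ValueError(
            f"need >= 3 participants with both gain levels in {group}/{feedback_type}"
        )
    diffs = (means["high"] - means["low"]).to_numpy()
    n = diffs.size
    comparison = f"{group} high vs low, {outcome} ({feedback_type})"
    if np.allclose(diffs, 0.0):
        return TestResult(
            name="paired_gain_test", statistic="t", value=0.0, p_value=1.0,
            df=float(n - 1), n=n, comparison=comparison,
            branch="degenerate: identical high and low values",
        )
    if np.ptp(diffs) == 0:  # constant non-zero shift: normality test undefined
        normal_p = 0.0
    else:
        normal_p = float(sps.shapiro(diffs).pvalue)
    if normal_p < alpha:
        res = sps.wilcoxon(diffs)
        return TestResult(
            name="paired_gain_test", statistic="W", value=float(res.statistic),
            p_value=float(res.pvalue), df=None, n=n, comparison=comparison,
            branch=f"wilcoxon (shapiro p = {normal_p:.3g})",
        )
    res = sps.ttest_rel(means["high"], means["low"])
    return TestResult(
        name="paired_gain_test", statistic="t", value=float(res.statistic),
        p_value=float(res.pvalue), df=float(n - 1), n=n, comparison=comparison,
        branch=f"paired t (shapiro p = {normal_p:.3g})",
    )


def anova_trials(
    features: pd.DataFrame,
    outcome: str = "rmse",
    factors: tuple[str, ...] = ("group", "feedback_type"),
) -> list[TestResult]:
    """Fixed-effects one-way ANOVA per factor on trial-level outcomes.

    Each factor is tested in its own one-way model (F with
    df = (k - 1, N - k)); trials are the unit of analysis, so residual
    degrees of freedom are on the trial scale.
    """
    out = []
    data = features.dropna(subset=[outcome])
    for factor in factors:
        levels = [g[outcome].to_numpy() for _, g in data.groupby(factor, sort=True)]
        k = len(levels)
        if k < 2:
            raise ValueError(f"factor {factor!r} has fewer than two levels")
        n_total = sum(len(v) for v in levels)
        pooled = np.concatenate(levels)
        if np.ptp(pooled) == 0:
            f_val, p_val = 0.0, 1.0
        else:
            res = sps.f_oneway(*levels)
            f_val, p_val = float(res.statistic), float(res.pvalue)
        out.append(
            TestResult(
                name="anova_trials", statistic="F", value=f_val, p_value=p_val,
                df=(float(k - 1), float(n_total - k)), n=n_total,
                comparison=f"{outcome} by {factor}",
            )
        )
    return out


def compare_covariates(
    values_by_group: dict,
    name: str = "covariate",
    alpha: float = 0.05,
    method: str = "auto",
) -> TestResult:
    """Between-group covariate comparison with a normality gate.

    With ``method='auto'``: Shapiro-Wilk per group; if either rejects at
    ``alpha`` (or is undefined for constant data), a Mann-Whitney U test
    is used, otherwise a two-sample t-test.  ``method='mwu'`` or
    ``'ttest'`` bypasses the gate.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    if method not in ("auto", "mwu", "ttest"):
        raise ValueError(f"unknown method {method!r}")
    (ga, a), (gb, b) = [(g, np.asarray(v, dtype=float)) for g, v in values_by_group.items()]
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    normal = method != "mwu"
    branch_notes = [] if method == "auto" else [f"forced {method}"]
    if method == "auto":
        for g, v in ((ga, a), (gb, b)):
            if np.ptp(v) == 0:
                normal = False
                branch_notes.append(f"{g} constant")
            else:
                p = float(sps.shapiro(v).pvalue)
                if p < alpha:
                    normal = False
                    branch_notes.append(f"{g} shapiro p = {p:.3g}")
    comparison = f"{ga} vs {gb}, {name}"
    if normal:
        res = sps.ttest_ind(a, b, equal_var=True)
        return TestResult(
            name="compare_covariates", statistic="t", value=float(res.statistic),
            p_value=float(res.pvalue), df=float(a.size + b.size - 2),
            n=(int(a.size), int(b.size)), comparison=comparison, branch="t-test",
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(
        name="compare_covariates", statistic="U", value=float(res.statistic),
        p_value=float(res.pvalue), df=None, n=(int(a.size), int(b.size)),
        comparison=comparison,
        branch="mann-whitney (" + "; ".join(branch_notes) + ")",
    )


def correlate(
    x,
    y,
    partial_covariate=None,
    groups=None,
    alpha: float = 0.05,
    name: str = "correlation",
) -> TestResult:
    """Gated correlation: Pearson when Shapiro-Wilk (and, with a grouping,
    Levene) allow it, Spearman otherwise; optionally partialling out a
    covariate by residualisation (via pingouin)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if partial_covariate is not None:
        z = np.asarray(partial_covariate, dtype=float)
        keep &= np.isfinite(z)
        z = np.asarray(partial_covariate, dtype=float)[keep]
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    gate_ps = [float(sps.shapiro(v).pvalue) for v in (x, y)]
    parametric = all(p >= alpha for p in gate_ps)
    if groups is not None and parametric:
        groups = np.asarray(groups)[keep]
        cells = [x[groups == g] for g in np.unique(groups)]
        if len(cells) > 1:
            parametric = float(sps.levene(*cells).pvalue) >= alpha
    method = "pearson" if parametric else "spearman"
    if partial_covariate is not None:
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        res = pg.partial_corr(data=df, x="x", y="y", covar="z", method=method)
        pcol = "p_val" if "p_val" in res.columns else "p-val"
        r, p = float(res["r"].iloc[0]), float(res[pcol].iloc[0])
        dof = float(x.size - 3)
        branch = f"partial {method}"
    else:
        if method == "pearson":
            res = sps.pearsonr(x, y)
        else:
            res = sps.spearmanr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        dof = float(x.size - 2)
        branch = method
    return TestResult(
        name="correlate", statistic="r" if method == "pearson" else "rho",
        value=r, p_value=p, df=dof, n=int(x.size), comparison=name, branch=branch,
    )


# ---------------------------------------------------------------------------
# sequential design power utility
# ---------------------------------------------------------------------------

@dataclass
class SequentialPowerResult:
    """Outcome of the simulated sequential design."""

    power_curve: dict  # n per group -> achieved power
    stopping_n: int | None  # smallest n with power >= target (None: cap reached)
    stopping_n_distribution: np.ndarray  # per-simulation first significant n (capped)
    power_target: float
    alpha: float
    n_max: int

    @property
    def achieved_power(self) -> float:
        n = self.stopping_n if self.stopping_n is not None else self.n_max
        return self.power_curve[n]


def sequential_power(
    effects: CohortEffects | None = None,
    alpha: float = 0.05,
    power_target: float = 0.80,
    n_max: int = 25,
    n_min: int = 4,
    n_sims: int = 200,
    seed=0,
    feedback_type: str = "vo",
    outcome: str = "delta_tremor_power",
    unit: str = "trial_pair",
) -> SequentialPowerResult:
    """Simulate the sequential accrual design.

    Each simulated study accrues participants (both groups in step) up to
    ``n_max`` per group; after each accrual step the primary between-group
    t-test on the high-minus-low tremor contrast is run.  Reported are the
    achieved power at every interim n, the smallest n per group reaching
    ``power_target`` (capped at ``n_max``), and the per-study distribution
    of the first significant interim analysis.
    """
    effects = CohortEffects.default() if effects is None else effects
    ss = np.random.SeedSequence(seed)
    sim_seeds = ss.spawn(n_sims)
    ns = list(range(n_min, n_max + 1))
    hits = np.zeros((n_sims, len(ns)), dtype=bool)
    for s in range(n_sims):
        _, feats = simulate_trial_features(n_max, effects, seed=sim_seeds[s])
        contrasts = build_contrasts(feats, unit=unit)
        sub = contrasts[contrasts["feedback_type"] == feedback_type]
        for i, n in enumerate(ns):
            pids = [f"pET{j + 1:02d}" for j in range(n)] + [f"HC{j + 1:02d}" for j in range(n)]
            res = group_ttest(sub[sub["pid"].isin(pids)], feedback_type, outcome)
            hits[s, i] = res.p_value < alpha
    power = hits.mean(axis=0)
    curve = {n: float(p) for n, p in zip(ns, power)}
    stopping_n = next((n for n, p in curve.items() if p >= power_target), None)
    first_sig = np.where(
        hits.any(axis=1), np.array(ns)[np.argmax(hits, axis=1)], n_max
    )
    return SequentialPowerResult(
        power_curve=curve, stopping_n=stopping_n,
        stopping_n_distribution=first_sig, power_target=power_target,
        alpha=alpha, n_max=n_max,
    )


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

def holm(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def run_full_stats(
    features: pd.DataFrame,
    participants: pd.DataFrame,
    alpha: float = 0.05,
    contrast_unit: str = "trial_pair",
    holm_correction: bool = False,
) -> tuple[pd.DataFrame, str]:
    """Run the whole battery on one cohort's feature table.

    Returns the results table (one test per row) and a plain-text report:
    between-group t-tests of the high-low contrast per modality for
    tremor power and pupil mean, within-group paired gain tests, one-way
    trial-level ANOVAs for the control outcomes, and covariate
    comparisons.
    """
    results: list[TestResult] = []
    lines: list[str] = ["Force tremor", "============"]
    contrasts = build_contrasts(features, unit=contrast_unit)

    for outcome, label in (
        ("delta_tremor_power", "tremor band power 4-12 Hz"),
        ("delta_pupil_mean", "baseline-corrected pupil mean"),
    ):
        if outcome == "delta_pupil_mean":
            lines += ["", "Pupillometry", "============"]
        lines.append(f"Between-group t-tests on high-low contrasts of {label}:")
        for ftype in FEEDBACK_TYPES:
            res = group_ttest(contrasts, ftype, outcome)
            results.append(res)
            lines.append(f"  {res}")
        lines.append("Within-group high vs low gain (participant means):")
        raw = "tremor_power" if outcome == "delta_tremor_power" else "pupil_mean"
        for group in ("pET", "HC"):
            for ftype in FEEDBACK_TYPES:
                res = paired_gain_test(features, group, ftype, raw, alpha=alpha)
                results.append(res)
                lines.append(f"  {res}")

    lines += ["", "Control outcomes (trial-level ANOVA)", "===================================="]
    for outcome in ("rmse", "mean_force", "voluntary_power"):
        for res in anova_trials(features, outcome):
            results.append(res)
            lines.append(f"  {res}")

    lines += ["", "Clinical covariates", "==================="]
    for cov in ("age", "tetras", "bdi"):
        vals = {
            g: participants.loc[participants["group"] == g, cov].to_numpy()
            for g in ("pET", "HC")
        }
        res = compare_covariates(vals, name=cov, alpha=alpha)
        results.append(res)
        lines.append(f"  {res}")

    table = pd.DataFrame([r.to_row() for r in results])
    if holm_correction:
        table["p_holm"] = holm(table["p_value"].to_numpy())
    return table, "\n".join(lines) + "\n"
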