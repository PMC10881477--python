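"""Statistics layer: contrasts, gated tests, ANOVA, correlation, power."""

import numpy as np
import pandas as pd
import pytest

from tremorgain.stats import (
    anova_trials,
    build_contrasts,
    compare_covariates,
    correlate,
    group_ttest,
    holm,
    paired_gain_test,
    run_full_stats,
    sequential_power,
)
from tremorgain.synth import CohortEffects, simulate_trial_features


@pytest.fixture(scope="module")
def default_cohort():
    return simulate_trial_features(14, CohortEffects.default(), seed=101)


def _contrast_frame(pet, hc, ftype="vo", outcome="delta_tremor_power"):
    rows = []
    for i, v in enumerate(pet):
        rows.append({"pid": f"pET{i:02d}", "group": "pET", "feedback_type": ftype,
                     "pair_index": 1, outcome: v})
    for i, v in enumerate(hc):
        rows.append({"pid": f"HC{i:02d}", "group": "HC", "feedback_type": ftype,
                     "pair_index": 1, outcome: v})
    return pd.DataFrame(rows)


class TestBuildContrasts:
    def test_trial_pair_counts(self, default_cohort):
        _, feats = default_cohort
        c = build_contrasts(feats, unit="trial_pair")
        for ftype in ("vo", "va", "ao"):
            assert (c["feedback_type"] == ftype).sum() == 56  # 2 pairs x 28

    def test_participant_unit_counts(self, default_cohort):
        _, feats = default_cohort
        c = build_contrasts(feats, unit="participant")
        assert (c["feedback_type"] == "vo").sum() == 28

    def test_identical_levels_give_zero_delta(self, default_cohort):
        _, feats = default_cohort
        flat = feats.copy()
        flat["tremor_power"] = 1.0
        flat["pupil_mean"] = 2.0
        c = build_contrasts(flat)
        np.testing.assert_allclose(c["delta_tremor_power"], 0.0)
        np.testing.assert_allclose(c["delta_pupil_mean"], 0.0)

    def test_missing_cell_dropped(self, default_cohort):
        _, feats = default_cohort
        trimmed = feats[
            ~((feats["pid"] == "pET01") & (feats["feedback_type"] == "vo")
              & (feats["gain_level"] == "high"))
        ]
        c = build_contrasts(trimmed)
        assert not ((c["pid"] == "pET01") & (c["feedback_type"] == "vo")).any()

    def test_unknown_unit_rejected(self, default_cohort):
        _, feats = default_cohort
        with pytest.raises(ValueError):
            build_contrasts(feats, unit="session")


class TestGroupTTest:
    def test_textbook_two_sample(self):
        c = _contrast_frame([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        res = group_ttest(c, "vo")
        assert res.value == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.n == (3, 3)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        c1 = _contrast_frame(a, b)
        c2 = _contrast_frame(3.0 * a + 5.0, 3.0 * b + 5.0)
        r1, r2 = group_ttest(c1, "vo"), group_ttest(c2, "vo")
        assert r1.value == pytest.approx(r2.value)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_null_calibration(self):
        """Type-I error of the between-group test ~ alpha on null cohorts."""
        rng = np.random.default_rng(1)
        hits = 0
        n_sims = 400
        for _ in range(n_sims):
            c = _contrast_frame(rng.normal(0, 1, 28), rng.normal(0, 1, 28))
            hits += group_ttest(c, "vo").p_value < 0.05
        assert 0.02 < hits / n_sims < 0.08

    def test_empty_group_rejected(self):
        c = _contrast_frame([1.0, 2.0], [])
        with pytest.raises(ValueError):
            group_ttest(c, "vo")


class TestPairedGainTest:
    @staticmethod
    def _features(low, high, group="pET", ftype="vo", outcome="tremor_power"):
        rows = []
        for i, (lo, hi) in enumerate(zip(low, high)):
            for k, (g, v) in enumerate((("low", lo), ("high", hi))):
                rows.append({"pid": f"{group}{i:02d}", "group": group,
                             "feedback_type": ftype, "trial_index": k + 1,
                             "gain_level": g, outcome: v})
        return pd.DataFrame(rows)

    def test_identical_values_report_no_effect(self):
        f = self._features([1.0] * 5, [1.0] * 5)
        res = paired_gain_test(f, "pET", "vo")
        assert res.p_value == 1.0
        assert "degenerate" in res.branch

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(2)
        lo, hi = rng.normal(1, 0.1, 12), rng.normal(1.3, 0.1, 12)
        f1 = self._features(lo, hi)
        f2 = self._features(hi, lo)
        r1 = paired_gain_test(f1, "pET", "vo")
        r2 = paired_gain_test(f2, "pET", "vo")
        assert abs(r1.value) == pytest.approx(abs(r2.value))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_power_at_one_sd_shift(self):
        """n = 14 pairs, shift = 1 SD: rejection rate >= 0.8 over 500 sims."""
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(500):
            lo = rng.normal(0.0, 1.0, 14)
            hi = lo + rng.normal(1.0, 1.0, 14)
            res = paired_gain_test(self._features(lo, hi), "pET", "vo")
            rejections += res.p_value < 0.05
        assert rejections / 500 >= 0.8

    def test_too_few_pairs_rejected(self):
        f = self._features([1.0, 2.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            paired_gain_test(f, "pET", "vo")


class TestAnova:
    def test_constant_outcome_gives_zero_f(self, default_cohort):
        _, feats = default_cohort
        flat = feats.copy()
        flat["rmse"] = 1.0
        for res in anova_trials(flat, "rmse"):
            assert res.value == 0.0 and res.p_value == 1.0

    def test_injected_main_effect_detected(self, default_cohort):
        _, feats = default_cohort
        bumped = feats.copy()
        bumped.loc[bumped["feedback_type"] == "ao", "mean_force"] += 1.0
        group_res, type_res = anova_trials(bumped, "mean_force")
        assert type_res.p_value < 0.001
        assert group_res.p_value > 0.001

    def test_df_on_trial_scale(self, default_cohort):
        _, feats = default_cohort
        group_res, type_res = anova_trials(feats, "rmse")
        assert group_res.df == (1.0, 334.0)
        assert type_res.df == (2.0, 333.0)

    def test_single_level_factor_rejected(self, default_cohort):
        _, feats = default_cohort
        only_pet = feats[feats["group"] == "pET"]
        with pytest.raises(ValueError):
            anova_trials(only_pet, "rmse", factors=("group",))


class TestCompareCovariates:
    def test_complete_separation(self):
        res = compare_covariates(
            {"pET": [1, 2, 3, 4, 5], "HC": [6, 7, 8, 9, 10]}, method="mwu"
        )
        assert res.statistic == "U"
        assert res.value == 0.0

    def test_identical_groups_midpoint(self):
        vals = list(range(10))
        res = compare_covariates({"pET": vals, "HC": vals}, method="mwu")
        assert res.value == pytest.approx(50.0)  # n^2/2
        assert res.p_value > 0.9

    def test_constant_group_forces_nonparametric(self):
        res = compare_covariates({"pET": [5.0] * 6, "HC": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        assert res.statistic == "U"
        assert "constant" in res.branch

    def test_t_branch_rate_under_normality(self):
        """Shapiro-Wilk gate passes normal data to the t-test >= 85% of runs."""
        rng = np.random.default_rng(4)
        t_branch = 0
        n_sims = 1000
        for _ in range(n_sims):
            res = compare_covariates(
                {"pET": rng.normal(0, 1, 14), "HC": rng.normal(0, 1, 14)}
            )
            t_branch += res.statistic == "t"
        assert t_branch / n_sims >= 0.85


class TestCorrelate:
    def test_perfect_linearity(self):
        x = np.linspace(0, 1, 30)
        res = correlate(x, 2.0 * x)
        assert res.value == pytest.approx(1.0)
        assert res.p_value < 1e-10

    def test_partial_removes_confound(self):
        """y = x + c z: partialling out z recovers the x-y core relation."""
        rng = np.random.default_rng(5)
        n = 200
        z = rng.normal(0, 1, n)
        x = rng.normal(0, 1, n) + 2.0 * z
        y = rng.normal(0, 1, n) + 2.0 * z
        raw = correlate(x, y)
        part = correlate(x, y, partial_covariate=z)
        assert raw.value > 0.5
        assert abs(part.value) < 0.2
        assert "partial" in part.branch

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            hits += correlate(rng.normal(size=20), rng.normal(size=20)).p_value < 0.05
        assert 0.02 < hits / n_sims < 0.08

    def test_nonnormal_input_routes_to_spearman(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 2, 60)
        y = x + rng.lognormal(0, 2, 60)
        res = correlate(x, y)
        assert res.statistic == "rho"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(10), np.arange(10))


class TestSequentialPower:
    def test_large_effect_stops_at_minimum(self):
        res = sequential_power(n_sims=40, seed=8, n_min=4, n_max=10)
        assert res.stopping_n == 4
        assert res.achieved_power >= 0.8

    def test_zero_effect_reports_cap(self):
        res = sequential_power(
            CohortEffects.null(), n_sims=60, seed=9, n_min=4, n_max=8
        )
        assert res.stopping_n is None
        assert all(p < 0.2 for p in res.power_curve.values())


class TestFullBattery:
    def test_row_count_and_validity(self, default_cohort):
        parts, feats = default_cohort
        table, report = run_full_stats(feats, parts)
        # 6 group t-tests, 12 paired tests, 6 ANOVA rows, 3 covariates
        assert len(table) == 27
        assert table["p_value"].between(0, 1).all()
        assert "Force tremor" in report and "Pupillometry" in report

    def test_alpha_plumbs_into_gates(self, default_cohort):
        parts, feats = default_cohort
        t1, _ = run_full_stats(feats, parts, alpha=0.05)
        t2, _ = run_full_stats(feats, parts, alpha=1e-12)
        # with alpha ~ 0 no normality gate can reject: every paired test
        # must run the parametric branch
        paired = t2[t2["test"] == "paired_gain_test"]
        assert (paired["statistic"] == "t").all()
        assert set(t1.columns) == set(t2.columns)

    def test_holm_option_adds_monotone_adjustment(self, default_cohort):
        parts, feats = default_cohort
        table, _ = run_full_stats(feats, parts, holm_correction=True)
        assert (table["p_holm"] >= table["p_value"] - 1e-15).all()

    def test_pid_relabeling_invariance(self, default_cohort):
        parts, feats = default_cohort
        ren = {p: f"S{i:03d}" for i, p in enumerate(parts["pid"])}
        t1, _ = run_full_stats(feats, parts)
        t2, _ = run_full_stats(
            feats.assign(pid=feats["pid"].map(ren)),
            parts.assign(pid=parts["pid"].map(ren)),
        )
        pd.testing.assert_series_equal(t1["p_value"], t2["p_value"])


def test_holm_textbook():
    np.testing.assert_allclose(
        holm([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
    )


def test_testresult_rejects_bad_p():
    from tremorgain import stats as tgs

    with pytest.raises(ValueError):
        tgs.TestResult(name="x", statistic="t", value=0.0, p_value=1.5)
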