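"""Odds ratios, univariate logistic regression, Mann-Whitney U, paired
differences and the within-subject ANOVA, against closed-form and
enumeration oracles."""

import numpy as np
import pytest

from lungrp.stats import (TwoByTwoTable, _exact_mwu_p, logistic_fit_univariate,
                          mann_whitney_u, odds_ratio, paired_mean_difference,
                          repeated_measures_anova)

# 2x2 rows with all margins positive whose printed ORs are reproduced exactly
# from counts (events/non-events x exposed/reference):
GENDER = TwoByTwoTable(a=6, b=15, c=20, d=142)       # female vs male
CHEMO = TwoByTwoTable(a=25, b=133, c=1, d=24)        # chemo yes vs no
STAGE4 = TwoByTwoTable(a=6, b=48, c=20, d=95)        # stage IV vs III
PTV_VOL = TwoByTwoTable(a=9, b=82, c=17, d=75)       # > median vs <= median


def table_to_arrays(t):
    exposed = np.r_[np.ones(t.a + t.b), np.zeros(t.c + t.d)]
    events = np.r_[np.ones(t.a), np.zeros(t.b), np.ones(t.c), np.zeros(t.d)]
    return exposed, events


class TestOddsRatio:
    @pytest.mark.parametrize("table,expected_or", [
        (GENDER, 2.84), (CHEMO, 4.51), (STAGE4, 0.59), (PTV_VOL, 0.48),
    ])
    def test_cohort_rows_reproduced(self, table, expected_or):
        assert round(odds_ratio(table).odds_ratio, 2) == expected_or

    def test_gender_row_full_inference(self):
        res = odds_ratio(GENDER)
        assert round(res.ci_low, 2) == 0.99
        assert round(res.ci_high, 2) == 8.17
        assert round(res.p_value, 3) == 0.053

    def test_symmetric_table_gives_unity(self):
        res = odds_ratio(TwoByTwoTable(10, 10, 10, 10))
        assert res.odds_ratio == 1.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_cell_flagged_with_degenerate_point(self):
        res = odds_ratio(TwoByTwoTable(a=0, b=14, c=20, d=95))  # no events exposed
        assert not res.estimable
        assert res.odds_ratio == 0.0
        assert np.isnan(res.ci_low)

    def test_row_and_column_swap_invariance(self):
        t = TwoByTwoTable(7, 12, 3, 20)
        swapped = TwoByTwoTable(t.d, t.c, t.b, t.a)  # both rows and both columns
        assert odds_ratio(swapped).odds_ratio == pytest.approx(odds_ratio(t).odds_ratio)

    def test_group_swap_inverts(self):
        t = TwoByTwoTable(7, 12, 3, 20)
        inv = TwoByTwoTable(t.c, t.d, t.a, t.b)
        assert odds_ratio(inv).odds_ratio == pytest.approx(1.0 / odds_ratio(t).odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)


class TestLogistic:
    @pytest.mark.parametrize("table", [GENDER, CHEMO, STAGE4, PTV_VOL])
    def test_binary_covariate_equals_closed_form(self, table):
        """ML logistic on a binary covariate is the 2x2 closed form (>= 6 digits)."""
        exposed, events = table_to_arrays(table)
        fit = logistic_fit_univariate(exposed, events)
        ref = odds_ratio(table)
        assert fit.or_per_unit == pytest.approx(ref.odds_ratio, rel=1e-8)
        assert fit.ci_low == pytest.approx(ref.ci_low, rel=1e-6)
        assert fit.ci_high == pytest.approx(ref.ci_high, rel=1e-6)
        assert fit.p_wald == pytest.approx(ref.p_value, abs=1e-8)

    def test_constant_covariate_flagged(self):
        fit = logistic_fit_univariate(np.ones(20), np.r_[np.ones(5), np.zeros(15)])
        assert not fit.converged
        assert np.isnan(fit.beta)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            logistic_fit_univariate(np.arange(10.0), np.zeros(10))

    def test_complete_separation_flagged_not_estimated(self):
        x = np.arange(20.0)
        y = (x >= 10).astype(float)
        fit = logistic_fit_univariate(x, y)
        assert not fit.converged
        assert np.isnan(fit.or_per_unit)

    def test_parameter_recovery(self):
        """n=5000 draws with true slope 0.35: estimate within 3 SE."""
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 5000)
        p = 1 / (1 + np.exp(-(-1.0 + 0.35 * x)))
        y = (rng.random(5000) < p).astype(float)
        fit = logistic_fit_univariate(x, y)
        se = (np.log(fit.ci_high) - np.log(fit.or_per_unit)) / 1.959963984540054
        assert abs(fit.beta - 0.35) < 3 * se


class TestMannWhitney:
    def test_identical_samples(self):
        a = np.arange(12.0)
        res = mann_whitney_u(a, a)
        assert res.u == len(a) ** 2 / 2
        assert res.p_value > 0.95

    def test_tiny_sample_exact_enumeration(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.method == "exact"
        assert res.u == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)  # 2 of the 6 rank splits

    def test_exact_handles_ties_with_midranks(self):
        res = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0])
        assert res.method == "exact"
        assert 0.0 < res.p_value <= 1.0

    def test_normal_approximation_close_to_enumeration_at_8_plus_8(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
            approx = mann_whitney_u(a, b)
            assert approx.method == "asymptotic"
            _, exact_p = _exact_mwu_p(a, b)
            assert abs(approx.p_value - exact_p) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mann_whitney_u([], [1.0])


class TestPairedDifference:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        res = paired_mean_difference(x, x)
        assert res.mean_difference == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_exact_constant_shift_degenerate(self):
        x = np.arange(10.0)
        res = paired_mean_difference(x + 1.7, x)
        assert res.mean_difference == pytest.approx(1.7)
        assert res.degenerate
        assert res.ci_low == res.ci_high == pytest.approx(1.7)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_mean_difference([1.0, 2.0], [1.0])

    def test_ci_coverage_of_true_offset(self):
        """95% CI for the 1.7 Gy MLD offset covers truth in >= 93/100 cohorts."""
        from lungrp.synthetic_data import CohortConfig, simulate_cohort
        covered = 0
        for seed in range(100):
            df = simulate_cohort(CohortConfig(n_patients=183, seed=seed))
            res = paired_mean_difference(df.mld_lungpgtv, df.mld_lungptv)
            covered += res.ci_low <= 1.7 <= res.ci_high
        assert covered >= 93


class TestRepeatedMeasuresAnova:
    def test_known_shifts_detected(self):
        rng = np.random.default_rng(8)
        subj = rng.normal(10, 2, (200, 1))
        data = subj + np.array([0.0, 1.7, 2.3]) + rng.normal(0, 0.7, (200, 3))
        res = repeated_measures_anova(data)
        assert res.df_condition == 2 and res.df_error == 398
        assert res.p_value < 0.001

    def test_identical_columns_flagged(self):
        col = np.arange(10.0)[:, None]
        res = repeated_measures_anova(np.repeat(col, 3, axis=1))
        assert res.degenerate
        assert np.isnan(res.f)

    def test_zero_error_variance_with_effect(self):
        col = np.arange(10.0)[:, None]
        data = np.hstack([col, col + 1.0, col + 2.0])
        res = repeated_measures_anova(data)
        assert res.degenerate
        assert res.p_value == 0.0

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(3)
        data = rng.normal(10, 2, (40, 1)) + np.array([0.0, 0.5, 1.0]) \
            + rng.normal(0, 1, (40, 3))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(40), 3),
            "cond": np.tile(["a", "b", "c"], 40),
            "y": data.ravel(),
        })
        ref = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subject")
        mine = repeated_measures_anova(data)
        assert mine.f == pytest.approx(float(ref["F"][0]), rel=1e-6)
        assert mine.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_null_type_one_error_near_nominal(self):
        """No condition effect: rejection rate at alpha=.05 close to 5%."""
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            data = rng.normal(0, 1, (30, 1)) + rng.normal(0, 1, (30, 3))
            rejections += repeated_measures_anova(data).p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            repeated_measures_anova(np.ones((2, 3)))
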