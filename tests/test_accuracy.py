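"""Diagnostic-accuracy statistics: exact intervals, Bayes identities,
likelihood ratios, subgroup tables and the aggregate report."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from oadx import (
    ContingencyTable,
    DomainError,
    UndefinedMetricError,
    accuracy_at_prevalence,
    build_contingency,
    clopper_pearson,
    full_report,
    likelihood_ratio_intervals,
    likelihood_ratios,
    overall_accuracy,
    predictive_values,
    sensitivity,
    specificity,
    subgroup_sensitivity,
    youden_index,
)

STUDY_CT = ContingencyTable(tp=47, fn=7, fp=13, tn=104)


class TestContingency:
    def test_study_counts_from_calls(self, fixture):
        calls, truth = fixture.calls_and_truth()
        assert build_contingency(calls, truth) == STUDY_CT

    def test_all_correct_toy(self):
        ct = build_contingency([True] * 3 + [False] * 3,
                               [True] * 3 + [False] * 3)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (3, 0, 0, 3)

    def test_swapping_calls_exchanges_fp_and_fn(self):
        calls = ["positive", "negative", "positive", "negative"]
        truth = [True, True, False, False]
        ct = build_contingency(calls, truth)
        flipped = build_contingency(
            ["negative" if c == "positive" else "positive" for c in calls], truth
        )
        assert (flipped.fp, flipped.fn) == (ct.fn, ct.fp) == (1, 1)

    def test_length_mismatch_and_empty(self):
        with pytest.raises(DomainError):
            build_contingency(["positive"], [True, False])
        with pytest.raises(DomainError):
            build_contingency([], [])


class TestPointMetrics:
    def test_study_values(self):
        assert sensitivity(STUDY_CT) == pytest.approx(0.8704, abs=5e-5)
        assert specificity(STUDY_CT) == pytest.approx(0.8889, abs=5e-5)
        assert overall_accuracy(STUDY_CT) == pytest.approx(0.8830, abs=5e-5)

    def test_degenerate(self):
        assert sensitivity(ContingencyTable(0, 5, 0, 5)) == 0.0
        with pytest.raises(UndefinedMetricError):
            sensitivity(ContingencyTable(0, 0, 5, 5))


class TestClopperPearson:
    def test_study_sensitivity_interval(self):
        ie = clopper_pearson(47, 54)
        assert ie.lower == pytest.approx(0.751, abs=5e-4)
        assert ie.upper == pytest.approx(0.946, abs=5e-4)

    def test_closed_form_at_zero_successes(self):
        ie = clopper_pearson(0, 10)
        assert ie.lower == 0.0
        assert ie.upper == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_closed_form_at_all_successes(self):
        ie = clopper_pearson(54, 54)
        assert ie.upper == 1.0
        assert ie.lower == pytest.approx(0.025 ** (1 / 54), abs=1e-12)

    def test_invalid_inputs(self):
        for args in [(-1, 10), (11, 10), (5, 0)]:
            with pytest.raises(DomainError):
                clopper_pearson(*args)
        with pytest.raises(DomainError):
            clopper_pearson(5, 10, confidence=1.0)

    @pytest.mark.parametrize("n", [10, 54, 117])
    def test_endpoints_match_binomial_tail_roots(self, n):
        """The beta-quantile bounds solve the defining binomial tail
        equations: P(X >= x | p = lower) = alpha/2 and
        P(X <= x | p = upper) = alpha/2."""
        alpha = 0.05
        for x in range(1, n, max(1, n // 7)):
            ie = clopper_pearson(x, n)
            lower = brentq(
                lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
                xtol=1e-12,
            )
            upper = brentq(
                lambda p: stats.binom.cdf(x, n, p) - alpha / 2, 1e-12, 1 - 1e-12,
                xtol=1e-12,
            )
            assert ie.lower == pytest.approx(lower, abs=1e-6)
            assert ie.upper == pytest.approx(upper, abs=1e-6)

    def test_conservative_coverage(self, rng):
        """The interval is conservative: exact coverage (binomial pmf sum
        over covering outcomes) is >= nominal everywhere on the grid, and
        seeded large-rep simulation agrees."""
        reps = 50_000
        for n in (10, 54, 117):
            lowers = np.array([clopper_pearson(x, n).lower for x in range(n + 1)])
            uppers = np.array([clopper_pearson(x, n).upper for x in range(n + 1)])
            for p in np.arange(0.1, 0.95, 0.1):
                pmf = stats.binom.pmf(np.arange(n + 1), n, p)
                exact_cov = pmf[(lowers <= p) & (p <= uppers)].sum()
                assert exact_cov >= 0.95 - 1e-12, (n, p, exact_cov)
                xs = rng.binomial(n, p, size=reps)
                covered = (lowers[xs] <= p) & (p <= uppers[xs])
                assert covered.mean() >= 0.95, (n, p, covered.mean())


class TestPredictiveValues:
    def test_study_sample_prevalence(self):
        ppv, npv = predictive_values(47 / 54, 104 / 117, 54 / 171)
        assert ppv == pytest.approx(0.783, abs=5e-4)
        assert npv == pytest.approx(0.937, abs=5e-4)

    def test_adjusted_to_intended_population(self):
        ppv, npv = predictive_values(47 / 54, 104 / 117, 0.60)
        assert ppv == pytest.approx(0.922, abs=5e-4)
        assert npv == pytest.approx(0.821, abs=5e-4)

    def test_perfect_test_limit(self):
        eps = 1e-9
        ppv, npv = predictive_values(1 - eps, 1 - eps, 0.3)
        assert ppv == pytest.approx(1.0, abs=1e-6)
        assert npv == pytest.approx(1.0, abs=1e-6)

    def test_prevalence_endpoints_rejected(self):
        for prev in (0.0, 1.0):
            with pytest.raises(DomainError):
                predictive_values(0.9, 0.9, prev)

    @given(
        tp=st.integers(1, 40), fn=st.integers(1, 40),
        fp=st.integers(1, 40), tn=st.integers(1, 40),
    )
    def test_bayes_consistency_with_column_ratios(self, tp, fn, fp, tn):
        """At the sample prevalence the Bayes formulas reproduce the
        direct column ratios tp/(tp+fp), tn/(tn+fn)."""
        ct = ContingencyTable(tp, fn, fp, tn)
        ppv, npv = predictive_values(
            sensitivity(ct), specificity(ct), ct.prevalence
        )
        assert ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
        assert npv == pytest.approx(tn / (tn + fn), abs=1e-12)

    @given(
        sens=st.floats(0.01, 0.99), spec=st.floats(0.01, 0.99),
        prev=st.floats(0.01, 0.99),
    )
    def test_posterior_odds_equal_prior_odds_times_lr(self, sens, spec, prev):
        ppv, _ = predictive_values(sens, spec, prev)
        lr_pos, _ = likelihood_ratios(sens, spec)
        prior_odds = prev / (1 - prev)
        posterior_odds = ppv / (1 - ppv)
        assert posterior_odds == pytest.approx(prior_odds * lr_pos, rel=1e-9)


class TestAccuracyAtPrevalence:
    def test_adjusted_and_sample_values(self):
        assert accuracy_at_prevalence(47 / 54, 104 / 117, 0.60) == pytest.approx(
            0.8778, abs=5e-5
        )
        assert accuracy_at_prevalence(
            47 / 54, 104 / 117, 54 / 171
        ) == pytest.approx(overall_accuracy(STUDY_CT), abs=1e-12)

    @given(s=st.floats(0, 1), prev=st.floats(0, 1))
    def test_equal_sens_spec_fixed_point(self, s, prev):
        assert accuracy_at_prevalence(s, s, prev) == pytest.approx(s, abs=1e-12)


class TestLikelihoodRatios:
    def test_study_values(self):
        lr_pos, lr_neg = likelihood_ratios(47 / 54, 104 / 117)
        assert lr_pos == pytest.approx(7.83, abs=5e-3)
        assert lr_neg == pytest.approx(0.1458, abs=5e-5)

    def test_uninformative_test(self):
        assert likelihood_ratios(0.5, 0.5) == (1.0, 1.0)

    def test_perfect_specificity_flagged_infinite(self):
        lr_pos, _ = likelihood_ratios(0.9, 1.0)
        assert math.isinf(lr_pos)
        ie_pos, _ = likelihood_ratio_intervals(ContingencyTable(9, 1, 0, 10))
        assert math.isinf(ie_pos.point) and math.isinf(ie_pos.upper)

    def test_log_method_intervals_on_study_counts(self):
        ie_pos, ie_neg = likelihood_ratio_intervals(STUDY_CT)
        # exp(ln LR +/- 1.96 SE) with SE from the four margins
        se_pos = math.sqrt(1 / 47 - 1 / 54 + 1 / 13 - 1 / 117)
        assert ie_pos.lower == pytest.approx(
            ie_pos.point * math.exp(-1.959964 * se_pos), rel=1e-5
        )
        assert 4 < ie_pos.lower < ie_pos.point < ie_pos.upper < 14


class TestYouden:
    def test_study_value_and_edges(self):
        assert youden_index(47 / 54, 104 / 117) == pytest.approx(0.759, abs=5e-4)
        assert youden_index(1, 1) == 1.0
        assert youden_index(0.5, 0.5) == 0.0


class TestSubgroupSensitivity:
    def test_kl_grade_table(self, fixture):
        specimens, calls = fixture.kl_specimens_and_calls()
        table = subgroup_sensitivity(specimens, calls, "kl_grade")
        by_grade = {r.group: r for r in table.rows}
        assert [by_grade[g].n for g in (2, 3, 4)] == [9, 25, 20]
        assert by_grade[2].sensitivity.point == pytest.approx(8 / 9)
        assert by_grade[3].sensitivity.point == pytest.approx(22 / 25)
        assert by_grade[4].sensitivity.point == pytest.approx(17 / 20)
        assert sum(r.n for r in table.rows) == 54
        assert sum(r.tp for r in table.rows) == 47
        assert table.excluded == ()

    def test_single_group_equals_overall_sensitivity(self, fixture):
        specimens, calls = fixture.kl_specimens_and_calls()
        table = subgroup_sensitivity(specimens, calls, lambda s: "all")
        assert table.rows[0].sensitivity.point == pytest.approx(
            sensitivity(STUDY_CT)
        )

    def test_zero_positive_group_has_zero_lower_bound(self, fixture):
        specimens, calls = fixture.kl_specimens_and_calls()
        calls = ["negative"] * len(calls)
        table = subgroup_sensitivity(specimens, calls, "kl_grade")
        for row in table.rows:
            assert row.sensitivity.point == 0.0
            assert row.sensitivity.lower == 0.0

    def test_missing_group_values_listed_not_dropped(self, fixture):
        specimens, calls = fixture.kl_specimens_and_calls()
        specimens[0] = type(specimens[0])(
            id="NOKL", comp=0.0, il8=0.0, diagnosis="OA", kl_grade=None
        )
        table = subgroup_sensitivity(specimens, calls, "kl_grade")
        assert table.excluded == ("NOKL",)
        assert sum(r.n for r in table.rows) == 53


class TestFullReport:
    def test_sample_prevalence_report(self):
        rep = full_report(STUDY_CT)
        assert rep.prevalence_used == pytest.approx(54 / 171)
        assert rep.sensitivity.point == pytest.approx(47 / 54)
        assert rep.accuracy.point == pytest.approx(151 / 171)
        assert rep.ppv.point == pytest.approx(47 / 60)
        assert rep.npv.point == pytest.approx(104 / 111)
        assert rep.youden_j == pytest.approx(47 / 54 + 104 / 117 - 1, abs=1e-15)

    def test_adjusted_prevalence_report(self):
        rep = full_report(STUDY_CT, prevalence=0.60)
        assert rep.ppv.point == pytest.approx(0.9216, abs=5e-4)
        assert rep.npv.point == pytest.approx(0.8205, abs=5e-4)
        assert rep.accuracy.point == pytest.approx(0.8778, abs=5e-4)

    def test_perfect_table(self):
        rep = full_report(ContingencyTable(1, 0, 0, 1))
        for ie in (rep.sensitivity, rep.specificity, rep.accuracy, rep.ppv, rep.npv):
            assert ie.point == 1.0
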