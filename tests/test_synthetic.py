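"""Calibrated cohort simulation: quantile fits, censoring mechanics,
reproducibility, and the built-in validation-count fixture."""

import math

import numpy as np
import pytest

from oadx import (
    CensorFlag,
    CohortSpec,
    DecisionLimits,
    DegenerateDataError,
    Diagnosis,
    DomainError,
    classify_cohort,
    empirical_roc,
    generate_cohort,
    generate_study,
    lognormal_from_median_iqr,
    roc_score,
    study_fixture,
)
from oadx.cohort_stats import median_iqr
from oadx.synthetic import TABLE_CALIBRATION, calibrate_marginal

Z75 = 0.6744897501960817


def spec_for(label, n=None, rank_correlation=0.0):
    cal = TABLE_CALIBRATION[label]
    cm, c1, c3 = cal["comp"]
    im, i1, i3 = cal["il8"]
    return CohortSpec(
        label=label, n=n or cal["n"],
        comp_median=cm, comp_q1=c1, comp_q3=c3,
        il8_median=im, il8_q1=i1, il8_q3=i3,
        rank_correlation=rank_correlation,
    )


class TestLognormalFromMedianIqr:
    def test_closed_form_on_oa_comp_row(self):
        mu, sigma = lognormal_from_median_iqr(3903.5, 2884.0, 4610.0)
        assert mu == pytest.approx(8.270, abs=5e-4)
        assert sigma == pytest.approx(0.348, abs=5e-4)

    def test_symmetric_multiplicative_case(self):
        m, k = 100.0, 3.0
        mu, sigma = lognormal_from_median_iqr(m, m / k, m * k)
        assert mu == pytest.approx(math.log(m))
        assert sigma == pytest.approx(math.log(k) / Z75)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DomainError):
            lognormal_from_median_iqr(10.0, 5.0, 5.0)  # q1 == q3
        with pytest.raises(DomainError):
            lognormal_from_median_iqr(10.0, -1.0, 20.0)
        with pytest.raises(DomainError):
            lognormal_from_median_iqr(10.0, 12.0, 20.0)  # q1 > median


class TestCalibrateMarginal:
    def test_uncensored_quartiles_match_exactly(self):
        m = calibrate_marginal(3903.5, 2884.0, 4610.0, 0.2, math.inf)
        q = m.quantile(np.array([0.25, 0.5, 0.75]))
        assert q == pytest.approx([2884.0, 3903.5, 4610.0], rel=1e-12)

    def test_left_censored_q1_puts_extra_mass_below_floor(self):
        # IL-8 with q1 at the LLOQ: latent P(X <= floor) exceeds 0.25
        m = calibrate_marginal(175.3, 102.4, 2768.0, 102.4, 40000.0)
        from scipy.stats import norm

        p_below = norm.cdf((math.log(102.4) - m.mu) / m.sigma_low)
        assert p_below > 0.25
        assert m.quantile(np.array([0.75]))[0] == pytest.approx(2768.0, rel=1e-12)

    def test_median_at_floor_majority_censored(self):
        m = calibrate_marginal(0.2, 0.2, 2442.0, 0.2, math.inf)
        from scipy.stats import norm

        p_below = norm.cdf((math.log(0.2) - m.mu) / m.sigma_low)
        assert p_below > 0.5
        assert m.quantile(np.array([0.75]))[0] == pytest.approx(2442.0, rel=1e-12)


class TestGenerateCohort:
    @pytest.mark.parametrize("label", list(Diagnosis)[:4])
    def test_recovers_every_calibration_cell_at_large_n(self, label):
        """Simulated median and IQR endpoints land within 5% of every
        published cohort/analyte calibration value at n = 10,000."""
        cohort = generate_cohort(spec_for(label, n=10_000), seed=2024)
        cal = TABLE_CALIBRATION[label]
        for analyte, values in (
            ("comp", [s.comp for s in cohort]),
            ("il8", [s.il8 for s in cohort]),
        ):
            target_m, target_q1, target_q3 = (
                cal[analyte][0], cal[analyte][1], cal[analyte][2]
            )
            s = median_iqr(values)
            assert abs(s.median - target_m) / target_m < 0.05, (label, analyte)
            assert abs(s.q1 - target_q1) / target_q1 < 0.05, (label, analyte)
            assert abs(s.q3 - target_q3) / target_q3 < 0.05, (label, analyte)

    def test_censor_flags_iff_values_at_limits(self):
        cohort = generate_cohort(spec_for(Diagnosis.NSA, n=2000), seed=5)
        for s in cohort:
            assert (s.comp == 0.2) == (s.comp_censor is CensorFlag.AT_LOWER_LIMIT)
            assert (s.il8 == 102.4) == (s.il8_censor is CensorFlag.AT_LOWER_LIMIT)
            assert (s.il8 == 40000.0) == (s.il8_censor is CensorFlag.AT_UPPER_LIMIT)

    def test_heavy_upper_censoring_when_median_near_ceiling(self):
        spec = CohortSpec(
            label=Diagnosis.NSA, n=500,
            comp_median=216.0, comp_q1=79.0, comp_q3=859.0,
            il8_median=39000.0, il8_q1=35000.0, il8_q3=40000.0,
        )
        cohort = generate_cohort(spec, seed=3)
        at_ceiling = sum(
            s.il8_censor is CensorFlag.AT_UPPER_LIMIT for s in cohort
        )
        assert at_ceiling > 0.25 * len(cohort)

    def test_same_seed_identical_datasets(self):
        a = generate_cohort(spec_for(Diagnosis.OA), seed=99)
        b = generate_cohort(spec_for(Diagnosis.OA), seed=99)
        assert a == b

    def test_invalid_spec_rejected(self):
        with pytest.raises(DomainError):
            CohortSpec(
                label=Diagnosis.OA, n=0,
                comp_median=100.0, comp_q1=50.0, comp_q3=200.0,
                il8_median=100.0, il8_q1=50.0, il8_q3=200.0,
            )
        with pytest.raises(DomainError):
            CohortSpec(
                label=Diagnosis.OA, n=5,
                comp_median=100.0, comp_q1=200.0, comp_q3=300.0,
                il8_median=100.0, il8_q1=50.0, il8_q3=200.0,
            )

    def test_rank_correlation_couples_analytes(self):
        corr_spec = spec_for(Diagnosis.CA, n=3000, rank_correlation=0.8)
        cohort = generate_cohort(corr_spec, seed=12)
        from scipy.stats import spearmanr

        rho = spearmanr(
            [s.comp for s in cohort], [s.il8 for s in cohort]
        ).statistic
        assert rho > 0.6


class TestGenerateStudy:
    def test_default_study_mirrors_cohort_design(self):
        study = generate_study(seed=0)
        assert len(study.specimens) == 171
        assert sum(study.truth) == 54
        by = {}
        for s in study.specimens:
            by[s.diagnosis] = by.get(s.diagnosis, 0) + 1
        assert by == {
            Diagnosis.OA: 54, Diagnosis.RA: 57, Diagnosis.CA: 30,
            Diagnosis.NSA: 30,
        }

    def test_single_cohort_dataset_rejected_by_roc(self):
        study = generate_study([spec_for(Diagnosis.OA)], seed=1)
        scores = [roc_score(s) for s in study.specimens]
        with pytest.raises(DegenerateDataError):
            empirical_roc(scores, study.truth)

    def test_seeds_change_ordering_not_composition(self):
        a = generate_study(seed=1)
        b = generate_study(seed=2)
        assert [s.diagnosis for s in a.specimens] != [
            s.diagnosis for s in b.specimens
        ]
        count = lambda st: sorted(
            (s.diagnosis.value, round(s.comp, 6)) for s in st.specimens
        )
        assert len(count(a)) == len(count(b)) == 171

    def test_positivity_monotone_in_ratio_limit_and_cohorts_ordered(self):
        """Sweeping the ratio gate: positivity decreases monotonically in
        every cohort and the OA cohort stays far above NSA throughout."""
        study = generate_study(seed=8)
        by_cohort = {}
        for s in study.specimens:
            by_cohort.setdefault(s.diagnosis, []).append(s)
        grid = [0.5, 1.0, 2.0, 4.0, 8.0]
        prev_rates = {d: 1.1 for d in by_cohort}
        for ratio_limit in grid:
            limits = DecisionLimits(1500.0, ratio_limit)
            rates = {}
            for d, specimens in by_cohort.items():
                _, summary = classify_cohort(specimens, limits)
                rates[d] = summary.positives / summary.n
            for d in rates:
                assert rates[d] <= prev_rates[d] + 1e-12
            assert rates[Diagnosis.OA] > rates[Diagnosis.NSA] + 0.5
            prev_rates = rates


class TestStudyFixture:
    def test_contingency_and_margins(self, fixture):
        ct = fixture.contingency
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (47, 7, 13, 104)
        assert ct.total == 171
        assert ct.condition_positive == 54

    def test_kl_groups_consistent_with_margins(self, fixture):
        assert sum(n for _, n, _ in fixture.kl_groups) == 54
        assert sum(tp for _, _, tp in fixture.kl_groups) == 47

    def test_cohort_positivity_rows(self, fixture):
        rows = dict(
            (d, (n, p)) for d, n, p in fixture.cohort_positivity
        )
        assert rows[Diagnosis.NSA] == (30, 0)
        assert rows[Diagnosis.OA] == (54, 47)
        assert sum(n for n, _ in rows.values()) == 171
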