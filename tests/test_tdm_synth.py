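"""Synthetic TDM cohorts and the monitoring analytics."""

import math

import numpy as np
import pytest
from scipy import stats

from erlopbpk.tdm_synth import (
    TDMConfig, TroughSummary, generate_cohort, group_compare,
    sampling_schedule, study_trough_summaries, summarize_troughs,
    threshold_classification, weekly_troughs,
)

# Printed per-patient mean troughs of the monitored cohort (ug/ml)
ARA_MEANS = [0.16, 0.37, 0.27, 0.06, 0.16]
NON_ARA_MEANS = [1.67, 0.89, 0.66, 1.78, 1.20]


def _summaries(ara, non):
    out = []
    for i, m in enumerate(ara):
        out.append(TroughSummary(f"a{i}", True, 5, m, 0.1, m - 0.05, m + 0.05))
    for i, m in enumerate(non):
        out.append(TroughSummary(f"n{i}", False, 5, m, 0.1, m - 0.05, m + 0.05))
    return out


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t statistic and two-sided p."""
    nx, ny = len(x), len(y)
    sx2 = sum((v - sum(x) / nx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - sum(y) / ny) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    t = (sum(x) / nx - sum(y) / ny) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2.0 * stats.t.sf(abs(t), nx + ny - 2)
    return t, p


class TestGroupCompare:
    def test_study_groups_significantly_different(self):
        t, p = group_compare(study_trough_summaries())
        assert p < 0.002

    def test_matches_textbook_pooled_formula(self):
        t_expect, p_expect = pooled_t_oracle(NON_ARA_MEANS, ARA_MEANS)
        t, p = group_compare(_summaries(ARA_MEANS, NON_ARA_MEANS))
        assert t == pytest.approx(t_expect, rel=1e-12)
        assert p == pytest.approx(p_expect, rel=1e-12)
        # frozen values from the hand computation of the printed means
        assert t == pytest.approx(4.6482, abs=1e-4)
        assert p == pytest.approx(0.0016485, abs=1e-6)

    def test_identical_groups_give_t0_p1(self):
        t, p = group_compare(_summaries([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_welch_variant_available(self):
        _, p_student = group_compare(study_trough_summaries(), "student")
        _, p_welch = group_compare(study_trough_summaries(), "welch")
        assert p_welch != p_student

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(_summaries([1.0], [2.0, 3.0]))

    def test_type_one_error_calibrated_under_null(self):
        """With no ARA effect, the pooled t-test on log-normal per-patient
        means rejects at ~5%; checked over 1500 null cohorts."""
        rng = np.random.default_rng(42)
        sigma = math.sqrt(math.log(1.0 + 0.30 ** 2))
        n_cohorts, rejections = 1500, 0
        for _ in range(n_cohorts):
            means = rng.lognormal(-0.5 * sigma ** 2, sigma, 10)
            summ = _summaries(means[:5], means[5:])
            _, p = group_compare(summ)
            rejections += p < 0.05
        rate = rejections / n_cohorts
        assert 0.025 <= rate <= 0.075


class TestThresholdClassification:
    def test_printed_table_classification(self):
        below, total, lo, hi = threshold_classification(
            study_trough_summaries(), 0.5)
        assert (below, total) == (5, 10)
        assert lo == pytest.approx(0.06) and hi == pytest.approx(1.78)

    def test_all_zero_means_all_below(self):
        s = _summaries([0.0, 0.0], [0.0, 0.0])
        assert threshold_classification(s, 0.5)[0] == 4

    def test_zero_threshold_none_below(self):
        s = _summaries(ARA_MEANS, NON_ARA_MEANS)
        assert threshold_classification(s, 0.0)[0] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            threshold_classification([], 0.5)


class TestSamplingSchedule:
    def test_matches_study_design(self):
        times, weeks = sampling_schedule(3)
        # day-1 dense grid
        for t in (0, 1, 2, 3, 4, 5, 6, 8, 24):
            assert t in times
        # days 2-8: trough + 4 h post
        for day in range(2, 9):
            assert 24.0 * (day - 1) in times
            assert 24.0 * (day - 1) + 4.0 in times
        # weekly troughs
        assert 336.0 in times and 504.0 in times
        assert np.all(np.diff(times) > 0)
        assert weeks[-1] == 3


@pytest.fixture(scope="module")
def small_cohort(drug):
    cfg = TDMConfig(n_patients_week1=6, n_patients_longterm=4,
                    weeks_longterm=2, seed=3, ara_fraction=0.5,
                    rtol=1e-5, atol=1e-7)
    return generate_cohort(cfg, drug), cfg


class TestGenerateCohort:
    def test_seeded_reproducibility(self, drug, small_cohort):
        cohort, cfg = small_cohort
        again = generate_cohort(cfg, drug)
        for a, b in zip(cohort.patients, again.patients):
            assert np.array_equal(a.concentrations, b.concentrations)
            assert a.ara_flag == b.ara_flag

    def test_zero_variability_patients_identical(self, drug):
        cfg = TDMConfig(n_patients_week1=3, n_patients_longterm=0,
                        weeks_longterm=1, seed=5, ara_fraction=0.0,
                        cv_clh=0.0, cv_weight=0.0, cv_gastric_emptying=0.0,
                        residual_cv=0.0, rtol=1e-5, atol=1e-7)
        cohort = generate_cohort(cfg, drug)
        ref = cohort.patients[0].concentrations
        for p in cohort.patients[1:]:
            assert p.concentrations == pytest.approx(ref, rel=1e-9)

    def test_ara_troughs_stochastically_lower(self, small_cohort):
        cohort, _ = small_cohort
        ara = [np.mean(weekly_troughs(p)) for p in cohort.patients
               if p.ara_flag and p.longterm]
        non = [np.mean(weekly_troughs(p)) for p in cohort.patients
               if not p.ara_flag and p.longterm]
        if ara and non:  # composition depends on the seed
            assert np.mean(ara) < np.mean(non)

    def test_concentrations_nonnegative(self, small_cohort):
        cohort, _ = small_cohort
        for p in cohort.patients:
            assert np.all(p.concentrations >= 0)


class TestSummarizeTroughs:
    def test_hand_arithmetic(self):
        from erlopbpk.tdm_synth import PatientRecord, TDMCohort
        times = np.array([168.0, 336.0, 504.0])
        rec = PatientRecord("p", False, 60.0, times,
                            np.array([1, 2, 3]), np.array([1.0, 2.0, 3.0]),
                            longterm=True)
        cohort = TDMCohort([rec], TDMConfig())
        s, = summarize_troughs(cohort)
        assert s.mean == 2.0 and s.sd == pytest.approx(1.0)
        assert (s.min, s.max, s.n) == (1.0, 3.0, 3)

    def test_order_statistics_invariant(self, small_cohort):
        cohort, _ = small_cohort
        for s in summarize_troughs(cohort):
            assert s.min <= s.mean <= s.max

    def test_single_trough_has_no_sd(self):
        from erlopbpk.tdm_synth import PatientRecord, TDMCohort
        rec = PatientRecord("p", False, 60.0, np.array([168.0]),
                            np.array([1]), np.array([0.7]), longterm=True)
        s, = summarize_troughs(TDMCohort([rec], TDMConfig()))
        assert s.sd is None and s.mean == pytest.approx(0.7)


def test_config_validation():
    with pytest.raises(ValueError):
        TDMConfig(ara_auc_reduction=1.5)
    with pytest.raises(ValueError):
        TDMConfig(activity_threshold=0.0)
    with pytest.raises(ValueError):
        TDMConfig(ara_fraction=-0.1)
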