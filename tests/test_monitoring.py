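import numpy as np
import pytest

import ctdna_monitor as cm
from ctdna_monitor.monitoring import PatientRecord, PlasmaSamplePoint, staircase_auc


def _quant(copies_per_ml, T=500_000):
    """QuantResult whose copies/ml plasma is approximately the target."""
    lam_target = copies_per_ml * 0.020 * 0.91e-3 / 20.0
    P = round(T * (1.0 - np.exp(-lam_target)))
    return cm.poisson_quantify(P, T)


def _sample(pid, t, rearr_per_ml, control_per_ml=1_000.0):
    rearr = {f"r{i}": _quant(v) for i, v in enumerate(rearr_per_ml)}
    return PlasmaSamplePoint(pid, t, rearr, _quant(control_per_ml))


def _record(pid, group, sample_specs, recurrence=None, last_fu=120.0, death=False):
    samples = [_sample(pid, t, r) for t, r in sample_specs]
    return PatientRecord(pid, group, {}, recurrence, last_fu, death, samples)


class TestSamplePositivity:
    def test_all_zero_negative(self):
        s = _sample("p", 12.0, [0, 0, 0, 0])
        assert not s.positive and s.ctdna_percent == 0.0

    def test_fraction_rule_max_over_rearrangements(self):
        s = _sample("p", 12.0, [50.0, 10.0], control_per_ml=1_000.0)
        assert s.positive
        assert s.ctdna_percent == pytest.approx(5.0, rel=0.05)

    def test_any_single_positive_rearrangement_makes_sample_positive(self):
        s = _sample("p", 12.0, [0, 0, 0, 0, 0, 40.0])
        assert s.positive

    def test_zero_control_non_evaluable(self):
        rearr = {"r0": _quant(50.0)}
        s = PlasmaSamplePoint("p", 12.0, rearr, _quant(0.0))
        assert not s.evaluable


class TestClassifyPatient:
    def test_one_positive_followup_classifies_positive(self):
        rec = _record("p", "EM", [(0.0, [0]), (12.0, [0]), (24.0, [80.0])], recurrence=30.0)
        assert cm.classify_patient(rec)

    def test_all_followups_negative_classifies_negative(self):
        rec = _record("p", "DF", [(0.0, [0]), (12.0, [0]), (24.0, [0])])
        assert not cm.classify_patient(rec)

    def test_presurgical_positive_excluded_from_classification(self):
        rec = _record("p", "EM", [(0.0, [100.0]), (12.0, [0]), (24.0, [0])], recurrence=30.0)
        assert not cm.classify_patient(rec)

    def test_no_followup_samples_non_evaluable(self):
        rec = _record("p", "DF", [(0.0, [0])])
        with pytest.raises(ValueError, match="post-surgery"):
            cm.classify_patient(rec)

    def test_invariant_to_extra_presurgical_samples(self):
        with_pre = _record("p", "EM", [(-1.0, [50.0]), (12.0, [60.0])], recurrence=30.0)
        without = _record("p", "EM", [(12.0, [60.0])], recurrence=30.0)
        assert cm.classify_patient(with_pre) == cm.classify_patient(without)


class TestConfusionAndRates:
    def test_printed_study_outcome_reproduced(self):
        """13/14 EM positive (one undetectable), 0/6 DF positive."""
        truth_pred = [(True, True)] * 13 + [(True, False)] + [(False, False)] * 6
        s = cm.confusion_and_rates(truth_pred)
        assert (s.tp, s.fn, s.tn, s.fp) == (13, 1, 6, 0)
        assert round(100 * s.sensitivity) == 93
        assert s.specificity == 1.0
        assert s.sensitivity_ci.lower == pytest.approx(0.6613, abs=2e-4)
        assert s.sensitivity_ci.upper == pytest.approx(0.9982, abs=2e-4)
        # specificity estimated at 1 -> one-sided lower bound
        assert s.specificity_ci.sidedness == "one_sided_lower"
        assert s.specificity_ci.lower == pytest.approx(0.05 ** (1 / 6), rel=1e-9)
        assert s.specificity_ci.upper == 1.0

    def test_perfect_small_cohort(self):
        truth_pred = [(True, True)] * 5 + [(False, False)] * 5
        s = cm.confusion_and_rates(truth_pred)
        assert s.sensitivity == 1.0 and s.specificity == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            cm.confusion_and_rates([(True, True)] * 3)


class TestRecurrenceTimes:
    def test_earliest_positive_followup(self):
        rec = _record("p", "EM", [(0.0, [0]), (13.0, [50.0]), (24.0, [90.0])], recurrence=49.0)
        assert cm.molecular_recurrence_time(rec) == 13.0

    def test_never_positive_absent(self):
        rec = _record("p", "EM", [(0.0, [0]), (12.0, [0])], recurrence=20.0)
        assert cm.molecular_recurrence_time(rec) is None
        assert cm.lead_time(rec) is None

    @pytest.mark.parametrize(
        "clinical,molecular,gain",
        [(49.0, 13.0, 36.0), (36.0, 23.0, 13.0), (61.3, 24.0, 37.3)],
    )
    def test_lead_time_from_study_narratives(self, clinical, molecular, gain):
        rec = _record(
            "p", "EM", [(0.0, [0]), (molecular, [50.0])], recurrence=clinical
        )
        lt = cm.lead_time(rec)
        assert lt["gain"] == pytest.approx(gain)
        assert lt["raw"] == pytest.approx(clinical - molecular)

    def test_molecular_after_clinical_clamped_to_zero(self):
        rec = _record("p", "EM", [(0.0, [0]), (24.0, [50.0])], recurrence=20.0)
        lt = cm.lead_time(rec)
        assert lt["gain"] == 0.0 and lt["raw"] == pytest.approx(-4.0)


class TestTimeToEvent:
    def test_intervals_and_grouping(self):
        em = _record("em", "EM", [(0.0, [0]), (13.0, [50.0]), (18.0, [0])], recurrence=21.0)
        df = _record("df", "DF", [(0.0, [0]), (12.0, [0])], last_fu=110.0)
        out = cm.time_to_event_summaries([em, df])
        assert out["EM_positive"]["intervals"] == [8.0]
        assert out["EM_negative"]["intervals"] == [3.0]
        assert out["DF_negative"]["intervals"] == [98.0]

    def test_sample_at_event_time_zero_interval(self):
        em = _record("em", "EM", [(0.0, [0]), (21.0, [50.0])], recurrence=21.0)
        out = cm.time_to_event_summaries([em])
        assert out["EM_positive"]["intervals"] == [0.0]


class TestROCSweep:
    def test_separable_cohort_attains_perfect_point_and_auc(self, small_cohort):
        roc = cm.roc_sweep(small_cohort)
        perfect = (roc.sensitivity == 1.0) & (roc.specificity == 1.0)
        assert perfect.any()
        assert roc.auc == pytest.approx(1.0)

    def test_threshold_zero_calls_everything_positive(self, small_cohort):
        # at 0 the negative cloud (centred on the 0 anchor) is half above
        # threshold, so every well fires: sensitivity 1, specificity 0
        roc = cm.roc_sweep(small_cohort, thresholds=[0.0])
        assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0

    def test_threshold_above_all_intensities_all_negative(self, small_cohort):
        # outside the ROC grid contract, but positive calling itself must
        # return zero above the maximum intensity
        well = small_cohort.patients[0].samples[-1].control_well
        P, T = well.counts_at(float(well.sorted_rel[-1]) + 1.0)
        assert P == 0 and T == well.n_droplets

    def test_grid_outside_unit_interval_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="within"):
            cm.roc_sweep(small_cohort, thresholds=[-0.1, 0.5])

    def test_default_threshold_reproduces_headline_confusion(self, small_cohort, small_records):
        truth_pred = [(r.group == "EM", cm.classify_patient(r)) for r in small_records]
        s = cm.confusion_and_rates(truth_pred)
        roc = cm.roc_sweep(small_cohort, thresholds=[0.5])
        assert roc.sensitivity[0] == pytest.approx(s.sensitivity)
        assert roc.specificity[0] == pytest.approx(s.specificity)

    def test_df_specificity_one_at_all_positive_thresholds(self, small_cohort):
        roc = cm.roc_sweep(small_cohort)
        assert np.all(roc.specificity[roc.thresholds > 0] == 1.0)


class TestStaircaseAUC:
    def test_perfect_and_random_curves(self):
        assert staircase_auc([0.0], [1.0]) == pytest.approx(1.0)
        assert staircase_auc([0.5], [0.5]) == pytest.approx(0.5)

    def test_refining_grid_never_decreases_auc(self):
        fpr = [0.0, 0.2, 0.6]
        tpr = [0.4, 0.8, 1.0]
        coarse = staircase_auc(fpr[:2], tpr[:2])
        fine = staircase_auc(fpr, tpr)
        assert fine >= coarse
        assert 0.0 <= fine <= 1.0
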