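"""Clinical read-outs: sample/patient positivity, lead times, ROC sweep.

A plasma sample is ctDNA positive when one or more tumor-specific
rearrangements has a molecular count above zero (pooled over replicate
wells); its ctDNA level is the maximal rearrangement concentration as a
percentage of the 2p14 total-cfDNA control.  A patient is classified
recurrence positive when any strictly post-surgery sample is positive;
presurgical samples are reported but excluded from classification.
Sensitivity/specificity carry Clopper-Pearson exact intervals (one-sided for
proportions estimated at 1).  The ROC sweep re-calls every droplet at each
relative-intensity threshold, re-quantifies, re-classifies, and integrates
the monotone hull of the operating points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import SimulatedCohort, SimulatedPatient
from .quant import QuantResult, pool_replicates, poisson_quantify
from .stats import ExactBinomialCI, clopper_pearson


@dataclass
class PlasmaSamplePoint:
    patient_id: str
    time_months: float  # <= 0 is presurgical
    rearr_quant: dict[str, QuantResult]
    control_quant: QuantResult
    ctdna_percent: float = field(init=False, default=0.0)
    positive: bool = field(init=False, default=False)
    evaluable: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self.positive, self.ctdna_percent, self.evaluable = sample_positivity(
            self.rearr_quant, self.control_quant
        )

    @property
    def max_rearrangement_copies_per_ml(self) -> float:
        vals = [q.copies_per_ml_plasma or 0.0 for q in self.rearr_quant.values()]
        return max(vals) if vals else 0.0


def sample_positivity(
    rearr_quant: dict[str, QuantResult], control_quant: QuantResult
) -> tuple[bool, float, bool]:
    """(positive, ctdna_percent, evaluable) for one time-point.

    Positive iff any rearrangement has pooled P > 0.  ctDNA percent is
    100 x max rearrangement concentration / control concentration; with zero
    control copies the sample is non-evaluable and the percent is 0.
    """
    positive = any(q.P > 0 for q in rearr_quant.values())
    ctrl = control_quant.copies_per_ml_plasma
    if ctrl is None or ctrl <= 0:
        return positive, 0.0, False
    best = max((q.copies_per_ml_plasma or 0.0 for q in rearr_quant.values()), default=0.0)
    return positive, 100.0 * best / ctrl, True


@dataclass
class PatientRecord:
    patient_id: str
    group: str  # 'EM' | 'DF' (truth)
    covariates: dict[str, str]
    time_to_recurrence: float | None
    time_to_last_followup: float
    death: bool
    samples: list[PlasmaSamplePoint]

    def __post_init__(self) -> None:
        times = [s.time_months for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if self.group == "EM" and self.time_to_recurrence is None:
            raise ValueError("EM patients need a recurrence time")

    def followup_samples(self) -> list[PlasmaSamplePoint]:
        return [s for s in self.samples if s.time_months > 0]


def classify_patient(record: PatientRecord) -> bool:
    """Recurrence-positive iff any post-surgery sample is ctDNA positive."""
    followup = record.followup_samples()
    if not followup:
        raise ValueError(f"{record.patient_id}: no post-surgery samples")
    return any(s.positive for s in followup)


@dataclass
class ClassificationSummary:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    sensitivity_ci: ExactBinomialCI
    specificity_ci: ExactBinomialCI


def confusion_and_rates(
    truth_and_pred: list[tuple[bool, bool]], level: float = 0.95
) -> ClassificationSummary:
    """Confusion counts and exact CIs from (true recurrence, predicted) pairs.

    The specificity interval is one-sided (lower bound only) when the point
    estimate is 1, matching the convention for proportions estimated at 1;
    both intervals are two-sided otherwise.
    """
    tp = sum(1 for t, p in truth_and_pred if t and p)
    fn = sum(1 for t, p in truth_and_pred if t and not p)
    tn = sum(1 for t, p in truth_and_pred if not t and not p)
    fp = sum(1 for t, p in truth_and_pred if not t and p)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both outcome groups must be non-empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = clopper_pearson(
        tp, tp + fn, level, "one_sided_lower" if sens == 1.0 else "two_sided"
    )
    spec_ci = clopper_pearson(
        tn, tn + fp, level, "one_sided_lower" if spec == 1.0 else "two_sided"
    )
    return ClassificationSummary(tp, tn, fp, fn, sens, spec, sens_ci, spec_ci)


def molecular_recurrence_time(record: PatientRecord) -> float | None:
    """Earliest post-surgery ctDNA-positive sample time, or None if never."""
    for s in record.followup_samples():
        if s.positive:
            return s.time_months
    return None


def lead_time(record: PatientRecord) -> dict | None:
    """Time gained by molecular over clinical detection of recurrence.

    Returns {'gain': max(0, clinical - molecular), 'raw': signed difference}
    or None when either time is missing.  Gains are clamped at zero (a
    molecular call after clinical detection gains nothing) but the raw
    difference is kept for auditing.
    """
    mol = molecular_recurrence_time(record)
    if mol is None or record.time_to_recurrence is None:
        return None
    raw = record.time_to_recurrence - mol
    return {"gain": max(0.0, raw), "raw": raw}


def time_to_event_summaries(records: list[PatientRecord]) -> dict:
    """Per-sample intervals from a test result to the event / last follow-up.

    For each post-surgery sample: interval = event time - sample time, where
    the event is clinical recurrence for EM patients and last follow-up for
    DF patients; grouped by (group, sample positivity) with medians and IQRs.
    """
    groups: dict[tuple[str, bool], list[float]] = {}
    for rec in records:
        event = (
            rec.time_to_recurrence if rec.group == "EM" else rec.time_to_last_followup
        )
        for s in rec.followup_samples():
            groups.setdefault((rec.group, s.positive), []).append(event - s.time_months)
    out = {}
    for (group, positive), vals in sorted(groups.items()):
        v = np.asarray(vals)
        out[f"{group}_{'positive' if positive else 'negative'}"] = {
            "n": int(v.size),
            "median": float(np.median(v)),
            "iqr": (float(np.percentile(v, 25)), float(np.percentile(v, 75))),
            "intervals": [float(x) for x in vals],
        }
    return out


# ------------------------------------------------------------------ quantification


def quantify_cohort(
    cohort: SimulatedCohort, threshold: float = 0.5
) -> list[PatientRecord]:
    """Pool replicate wells, Poisson-quantify, and assemble patient records."""
    spec = cohort.spec
    records = []
    for pat in cohort.patients:
        points = []
        for s in pat.samples:
            rearr = {}
            for assay, wells in s.rearr_wells.items():
                P, T = pool_replicates([w.counts_at(threshold) for w in wells])
                rearr[assay] = poisson_quantify(
                    P, T, v_r=spec.v_r, v_i=spec.v_i, v_d=spec.v_d,
                    plasma_equiv_ml=spec.plasma_equiv_ml,
                )
            cp, ct = s.control_well.counts_at(threshold)
            control = poisson_quantify(
                cp, ct, v_r=spec.v_r, v_i=spec.v_i, v_d=spec.v_d,
                plasma_equiv_ml=spec.plasma_equiv_ml,
            )
            points.append(PlasmaSamplePoint(pat.patient_id, s.time_months, rearr, control))
        records.append(
            PatientRecord(
                pat.patient_id, pat.group, pat.covariates, pat.time_to_recurrence,
                pat.time_to_last_followup, pat.death, points,
            )
        )
    return records


# -------------------------------------------------------------------- ROC sweep


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def operating_points(self) -> np.ndarray:
        """(1 - specificity, sensitivity) per threshold."""
        return np.column_stack([1.0 - self.specificity, self.sensitivity])


def staircase_auc(fpr, tpr) -> float:
    """Trapezoidal area under the monotone hull, endpoints (0,0),(1,1) added."""
    pts = np.column_stack([fpr, tpr])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    hull = np.maximum.accumulate(pts[:, 1])
    return float(np.trapezoid(hull, pts[:, 0]))


def roc_sweep(
    cohort: SimulatedCohort,
    thresholds=None,
) -> ROCResult:
    """Re-call, re-quantify and re-classify the cohort at each threshold.

    The default grid steps the relative-intensity threshold from 0 to 1 in
    0.05 increments.  At each threshold every droplet is re-dichotomized,
    duplicates re-pooled, each time-point re-represented by its
    maximal-concentration rearrangement, and every patient re-classified;
    the AUC integrates the monotone hull of the resulting points.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 1.0001, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.min() < 0 or thresholds.max() > 1:
        raise ValueError("threshold grid must lie within [0, 1]")

    truth = np.array([p.group == "EM" for p in cohort.patients])
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = np.array(
            [_patient_positive_at(p, thr) for p in cohort.patients]
        )
        tp = int(np.sum(pred & truth))
        fn = int(np.sum(~pred & truth))
        tn = int(np.sum(~pred & ~truth))
        fp = int(np.sum(pred & ~truth))
        sens[i] = tp / (tp + fn) if tp + fn else np.nan
        spec[i] = tn / (tn + fp) if tn + fp else np.nan
    auc = staircase_auc(1.0 - spec, sens)
    return ROCResult(thresholds, sens, spec, auc)


def _patient_positive_at(pat: SimulatedPatient, threshold: float) -> bool:
    for s in pat.samples:
        if s.time_months <= 0:
            continue
        for wells in s.rearr_wells.values():
            if sum(w.counts_at(threshold)[0] for w in wells) > 0:
                return True
    return False
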