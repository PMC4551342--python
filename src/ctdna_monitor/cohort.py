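"""Synthetic patient cohort: plasma time courses as droplet-level ddPCR data.

Emulates a monitoring study of primary breast cancer: 14 eventual-metastatic
(EM) and 6 long-term disease-free (DF) patients, each with a presurgical
plasma sample and 3-5 follow-up samples, 4-6 personalized rearrangement
assays run in duplicate wells per time-point, and one control assay on a
copy-number-stable region (2p14) quantifying total cell-free DNA.  EM
patients carry a latent exponential ctDNA trajectory: the tumor-derived
fraction is zero until a hidden onset time and doubles every few months
afterwards, so molecular positivity precedes the clinical recurrence time.
DF patients' tumor-target copy numbers are identically zero after surgery.

Every well is simulated at the droplet level (mean 25,704, SD 2,320 droplets
per well) and stored as sorted control-normalized intensities, which lets
threshold sweeps re-call droplets cheaply.  All randomness flows from one
seed; identical specs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .droplets import (
    DEFAULT_INTENSITY_MODEL,
    DROPLETS_PER_WELL_MEAN,
    DROPLETS_PER_WELL_SD,
    simulate_control_wells,
    simulate_droplets,
)
from .quant import (
    PLASMA_EQUIV_ML,
    V_DROPLET_UL,
    V_INPUT_UL,
    V_REACTION_UL,
    normalize_droplets,
)

CONTROL_ASSAY = "2p14"


@dataclass
class CohortSpec:
    """Generator parameters; the defaults are the study conditions."""

    n_em: int = 14
    n_df: int = 6
    seed: int = 0
    # assays
    n_rearrangements_range: tuple[int, int] = (4, 6)
    n_replicate_wells: int = 2
    droplets_mean: float = DROPLETS_PER_WELL_MEAN
    droplets_sd: float = DROPLETS_PER_WELL_SD
    droplets_min: int = 1000
    intensity_model: tuple[float, float, float, float] = DEFAULT_INTENSITY_MODEL
    # volumes
    v_r: float = V_REACTION_UL
    v_i: float = V_INPUT_UL
    v_d: float = V_DROPLET_UL
    plasma_equiv_ml: float = PLASMA_EQUIV_ML
    # total cell-free DNA baseline (copies/ml plasma), log-normal across patients
    control_log_mean: float = float(np.log(1450.0))
    control_log_sd: float = 0.75
    control_sample_jitter_sd: float = 0.3
    # EM ctDNA kinetics: zero before onset, then f0 * 2^((t-onset)/doubling)
    onset_months_range: tuple[float, float] = (6.0, 26.0)
    fraction_at_onset: float = 0.005
    doubling_time_months: float = 3.0
    max_fraction: float = 0.7
    absent_rearrangement_prob: float = 0.25
    presurgical_positive_prob: float = 0.3
    presurgical_fraction_range: tuple[float, float] = (0.002, 0.02)
    # clinical course
    recurrence_months_range: tuple[float, float] = (14.0, 61.0)
    df_followup_months_range: tuple[float, float] = (109.0, 113.0)
    em_death_prob: float = 0.5
    core_followup_months: tuple[float, ...] = (12.0, 24.0, 36.0)
    optional_followup_months: tuple[float, ...] = (4.0, 8.0)

    def validate(self) -> None:
        if self.n_em < 0 or self.n_df < 0 or self.n_em + self.n_df == 0:
            raise ValueError("cohort must contain patients")
        lo, hi = self.n_rearrangements_range
        if not 1 <= lo <= hi:
            raise ValueError("bad rearrangement count range")
        if min(self.v_r, self.v_i, self.v_d, self.plasma_equiv_ml) <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class SimulatedWell:
    assay_id: str
    sample_id: str
    replicate: int
    sorted_rel: np.ndarray  # sorted normalized intensities
    true_copies: int  # copies among analyzed droplets (hidden truth)

    @property
    def n_droplets(self) -> int:
        return int(self.sorted_rel.size)

    def counts_at(self, threshold: float) -> tuple[int, int]:
        """(P, T) at a relative-intensity threshold (inclusive)."""
        idx = int(np.searchsorted(self.sorted_rel, threshold, side="left"))
        return self.sorted_rel.size - idx, self.sorted_rel.size


@dataclass
class SimulatedSample:
    patient_id: str
    time_months: float
    rearr_wells: dict[str, list[SimulatedWell]]
    control_well: SimulatedWell
    true_fractions: dict[str, float]  # per-assay tumor fraction of cfDNA
    control_copies_per_ml: float

    @property
    def tumor_truth_copies(self) -> dict[str, int]:
        return {a: sum(w.true_copies for w in ws) for a, ws in self.rearr_wells.items()}


@dataclass
class SimulatedPatient:
    patient_id: str
    group: str  # 'EM' | 'DF'
    covariates: dict[str, str]
    time_to_recurrence: float | None
    time_to_last_followup: float
    death: bool
    onset_months: float | None
    samples: list[SimulatedSample]
    rearrangement_assays: list[str]


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    patients: list[SimulatedPatient]

    @property
    def assay_ids(self) -> list[str]:
        out = []
        for p in self.patients:
            out.extend(p.rearrangement_assays)
        return out


_COVARIATE_LEVELS = {
    "T": ("T1", "T2", "T3"),
    "N": ("N0", "N1", "N2", "N3"),
    "grade": ("G1", "G2", "G3"),
    "ER": ("pos", "neg"),
    "PR": ("pos", "neg"),
    "HER2": ("neg", "pos"),
}


def _draw_covariates(rng: np.random.Generator, is_em: bool) -> dict[str, str]:
    # EM tumors mildly enriched for adverse features; not used for simulation
    shift = 0.15 if is_em else 0.0
    cov = {}
    for name, levels in _COVARIATE_LEVELS.items():
        p = np.full(len(levels), 1.0 / len(levels))
        p[-1] += shift
        p[0] -= shift
        cov[name] = str(rng.choice(levels, p=p / p.sum()))
    return cov


def _well(
    spec: CohortSpec,
    rng: np.random.Generator,
    assay_id: str,
    sample_id: str,
    replicate: int,
    copies_mean: float,
    controls,
) -> SimulatedWell:
    n_droplets = max(
        spec.droplets_min, int(rng.normal(spec.droplets_mean, spec.droplets_sd))
    )
    copies = int(rng.poisson(copies_mean))
    ds = simulate_droplets(
        copies,
        n_droplets=n_droplets,
        intensity_model=spec.intensity_model,
        seed=rng,
        assay_id=assay_id,
        sample_id=sample_id,
    )
    norm = normalize_droplets(ds, *controls)
    rel = np.sort(norm.rel_intensities).astype(np.float32)
    return SimulatedWell(assay_id, sample_id, replicate, rel, copies)


def trajectory_fraction(
    t: float, onset: float, f0: float, doubling: float, cap: float
) -> float:
    """Tumor fraction of cfDNA at follow-up time t (months after surgery)."""
    if t < onset:
        return 0.0
    return float(min(cap, f0 * 2.0 ** ((t - onset) / doubling)))


def simulate_cohort(spec: CohortSpec | None = None) -> SimulatedCohort:
    """Generate the full droplet-level cohort with ground truth."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    analyzed_frac_per_droplet = spec.v_d / spec.v_r  # share of reaction per droplet

    patients: list[SimulatedPatient] = []
    groups = ["EM"] * spec.n_em + ["DF"] * spec.n_df
    for idx, group in enumerate(groups, start=1):
        pid = f"{group}{idx if group == 'EM' else idx - spec.n_em}"
        is_em = group == "EM"
        n_rearr = int(
            rng.integers(spec.n_rearrangements_range[0], spec.n_rearrangements_range[1] + 1)
        )
        assays = [f"{pid}_r{j+1}" for j in range(n_rearr)]

        n_opt = int(rng.integers(0, len(spec.optional_followup_months) + 1))
        opts = sorted(
            rng.choice(spec.optional_followup_months, size=n_opt, replace=False).tolist()
        )
        times = [0.0] + opts + sorted(spec.core_followup_months)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")

        if is_em:
            recurrence = float(rng.uniform(*spec.recurrence_months_range))
            onset = float(rng.uniform(*spec.onset_months_range))
            death = bool(rng.random() < spec.em_death_prob)
            last_fu = recurrence + float(rng.uniform(6.0, 36.0))
        else:
            recurrence, onset = None, None
            death = False
            last_fu = float(rng.uniform(*spec.df_followup_months_range))

        weights = rng.dirichlet(np.ones(n_rearr))
        absent = rng.random(n_rearr) < spec.absent_rearrangement_prob
        if absent.all():
            absent[int(rng.integers(n_rearr))] = False
        weights = np.where(absent, 0.0, weights)
        weights = weights / weights.sum()
        # weights scale each assay's share of the total tumor fraction
        rel_weight = weights / weights.max()

        presurg_fraction = 0.0
        if is_em and rng.random() < spec.presurgical_positive_prob:
            presurg_fraction = float(rng.uniform(*spec.presurgical_fraction_range))

        baseline_per_ml = float(
            np.exp(rng.normal(spec.control_log_mean, spec.control_log_sd))
        )

        controls = {
            assay: simulate_control_wells(
                assay,
                n_droplets=int(spec.droplets_mean),
                intensity_model=spec.intensity_model,
                seed=rng,
            )
            for assay in assays + [f"{pid}_{CONTROL_ASSAY}"]
        }

        samples: list[SimulatedSample] = []
        for t in times:
            sample_id = f"{pid}_m{t:g}"
            control_per_ml = baseline_per_ml * float(
                np.exp(rng.normal(0.0, spec.control_sample_jitter_sd))
            )
            if not is_em:
                total_fraction = 0.0
            elif t <= 0:
                total_fraction = presurg_fraction
            else:
                total_fraction = trajectory_fraction(
                    t, onset, spec.fraction_at_onset,
                    spec.doubling_time_months, spec.max_fraction,
                )
            fractions = {a: total_fraction * rel_weight[j] for j, a in enumerate(assays)}

            control_assay = f"{pid}_{CONTROL_ASSAY}"
            ctrl_rxn = control_per_ml * spec.plasma_equiv_ml
            n_ctrl_droplets = spec.droplets_mean  # expectation for copy scaling
            control_well = _well(
                spec, rng, control_assay, sample_id, 0,
                ctrl_rxn * n_ctrl_droplets * analyzed_frac_per_droplet,
                controls[control_assay],
            )
            rearr_wells: dict[str, list[SimulatedWell]] = {}
            for a in assays:
                per_rxn = fractions[a] * control_per_ml * spec.plasma_equiv_ml
                rearr_wells[a] = [
                    _well(
                        spec, rng, a, sample_id, rep,
                        per_rxn * spec.droplets_mean * analyzed_frac_per_droplet,
                        controls[a],
                    )
                    for rep in range(spec.n_replicate_wells)
                ]
            samples.append(
                SimulatedSample(
                    pid, t, rearr_wells, control_well, fractions, control_per_ml
                )
            )

        patients.append(
            SimulatedPatient(
                pid, group, _draw_covariates(rng, is_em), recurrence, last_fu,
                death, onset, samples, assays,
            )
        )
    return SimulatedCohort(spec, patients)


def simulate_outcome_covariates(
    n: int,
    or_per_doubling: float,
    seed: int = 0,
    intercept: float = 0.0,
    zero_fraction: float = 0.3,
    floor: float = 0.01,
    log2_percent_mean: float = 2.0,
    log2_percent_sd: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level (ctDNA percent, outcome) pairs with log2-linear risk.

    A fraction of patients has undetectable ctDNA (floored at ``floor``
    percent); the rest draw log2 percent from a normal.  Outcomes are
    Bernoulli with logit = intercept + log2(OR) * log2(percent).  Used for
    parameter-recovery checks of the regression machinery.
    """
    if or_per_doubling <= 0:
        raise ValueError("odds ratio must be positive")
    rng = np.random.default_rng(seed)
    zero = rng.random(n) < zero_fraction
    log2p = rng.normal(log2_percent_mean, log2_percent_sd, size=n)
    percent = np.where(zero, 0.0, 2.0**log2p)
    x = np.log2(np.maximum(percent, floor))
    beta1 = np.log(or_per_doubling)  # logit slope per unit of log2(percent)
    eta = intercept + beta1 * x
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return percent, y
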