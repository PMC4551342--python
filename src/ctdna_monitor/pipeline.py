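"""End-to-end orchestration: simulate -> call -> quantify -> monitor -> regress."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .caller import call_rearrangements
from .cohort import CohortSpec, simulate_cohort
from .copynumber import copy_number_track
from .genome import make_toy_genome, plant_rearrangements, random_rearrangements
from .monitoring import (
    confusion_and_rates,
    classify_patient,
    lead_time,
    molecular_recurrence_time,
    quantify_cohort,
    roc_sweep,
)
from .reads import simulate_read_pairs
from .stats import (
    aic_firth,
    ctdna_covariate,
    default_transforms,
    firth_logistic,
    select_transform,
)

log = logging.getLogger("ctdna")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips through YAML losslessly."""

    seed: int = 1
    out_dir: str = "report"
    # rearrangement-calling demo (one synthetic tumor)
    n_chromosomes: int = 2
    chromosome_length: int = 60_000
    sv_types: tuple[str, ...] = ("translocation", "deletion", "inversion")
    coverage: float = 10.0
    read_length: int = 100
    insert_median: float = 500.0
    error_rate: float = 0.0
    # ddPCR / monitoring
    n_em: int = 14
    n_df: int = 6
    droplets_per_well: float = 25_704.0
    v_r: float = 20.0
    v_i: float = 4.0
    v_d: float = 0.91e-3
    threshold: float = 0.5
    roc_step: float = 0.05
    floor_percent: float = 0.01

    def validate(self) -> None:
        if min(self.v_r, self.v_i, self.v_d) <= 0:
            raise ValueError("volumes must be positive")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")
        if not 0 < self.roc_step <= 1:
            raise ValueError("ROC grid step must lie in (0, 1]")
        if self.coverage <= 0 or self.chromosome_length < 10_000:
            raise ValueError("need positive coverage and chromosomes >= 10 kb")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write a versioned report bundle.

    Returns the summary dict (also written as summary.json).  Output is
    deterministic for a fixed config: rerunning writes byte-identical JSON.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        # ---- stage 1: synthetic tumor + reads ------------------------------
        genome = make_toy_genome(
            config.n_chromosomes, config.chromosome_length, seed=config.seed
        )
        events = random_rearrangements(genome, list(config.sv_types), seed=config.seed + 1)
        donor = plant_rearrangements(genome, events)
        tumor_reads = simulate_read_pairs(
            donor.genome, config.coverage, config.read_length,
            config.insert_median, error_rate=config.error_rate, seed=config.seed + 2,
        )
        normal_reads = simulate_read_pairs(
            genome, config.coverage, config.read_length,
            config.insert_median, error_rate=config.error_rate,
            seed=config.seed + 3, id_prefix="norm",
        )
        cio.write_fasta(genome, out / "reference.fa")
        cio.write_fastq_pair(tumor_reads, out / "tumor_r1.fq", out / "tumor_r2.fq")

        cohort = simulate_cohort(
            CohortSpec(
                n_em=config.n_em, n_df=config.n_df, seed=config.seed + 4,
                droplets_mean=config.droplets_per_well,
                v_r=config.v_r, v_i=config.v_i, v_d=config.v_d,
            )
        )

        # ---- stage 2: rearrangement calling --------------------------------
        stage = "call"
        result = call_rearrangements(tumor_reads, genome, normal_reads=normal_reads)
        cio.write_bedpe(result.calls, out / "calls.bedpe", out / "calls.json")
        track = copy_number_track(result.alignment_pairs, genome)
        cio.write_bedgraph(track, out / "coverage.bedgraph")

        # ---- stage 3: quantification ---------------------------------------
        stage = "quantify"
        records = quantify_cohort(cohort, threshold=config.threshold)
        cio.quant_table(records).to_csv(out / "quant.csv", index=False)
        cio.cohort_table(records).to_csv(out / "cohort.csv", index=False)

        # ---- stage 4: monitoring -------------------------------------------
        stage = "monitor"
        truth_pred = [(r.group == "EM", classify_patient(r)) for r in records]
        summary_cls = confusion_and_rates(truth_pred)
        roc = roc_sweep(cohort, np.arange(0.0, 1.0 + 1e-9, config.roc_step))
        leads = {
            r.patient_id: lead_time(r)
            for r in records
            if r.group == "EM" and lead_time(r) is not None
        }
        mol_times = {
            r.patient_id: molecular_recurrence_time(r) for r in records
        }

        # ---- stage 5: regression -------------------------------------------
        stage = "regress"
        covars = ctdna_covariate(records, "time_to_recurrence", floor=config.floor_percent)
        raw = {}
        for rec in records:
            if rec.patient_id in covars:
                raw[rec.patient_id] = 2.0 ** covars[rec.patient_id]
        pids = sorted(raw)
        percent = np.array([raw[p] for p in pids])
        outcomes = {
            "recurrence": [int(next(r.group == "EM" for r in records if r.patient_id == p)) for p in pids],
            "death": [int(next(r.death for r in records if r.patient_id == p)) for p in pids],
        }
        transform, aic_sums = select_transform(
            percent, outcomes, default_transforms(config.floor_percent)
        )
        regress = {}
        for name, y in outcomes.items():
            x = transform.apply(percent)
            fit = firth_logistic(np.asarray(y), x[:, None])
            regress[name] = {
                "odds_ratio": float(fit.odds_ratios[1]),
                "coef": float(fit.coef[1]),
                "se": float(fit.se[1]),
                "wald_p": float(fit.wald_p[1]),
                "converged": bool(fit.converged),
                "aic": aic_firth(fit),
            }
    except Exception as exc:  # noqa: BLE001 - abort reports the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r} (outputs in {out})") from exc

    summary = {
        "seed": config.seed,
        "calling": {
            "n_planted": len(events),
            "n_calls": len(result.calls),
            "n_germline_removed": result.n_germline_removed,
        },
        "classification": {
            "tp": summary_cls.tp, "tn": summary_cls.tn,
            "fp": summary_cls.fp, "fn": summary_cls.fn,
            "sensitivity": round(summary_cls.sensitivity, 6),
            "specificity": round(summary_cls.specificity, 6),
            "sensitivity_ci": [round(summary_cls.sensitivity_ci.lower, 6),
                               round(summary_cls.sensitivity_ci.upper, 6)],
            "specificity_ci": [round(summary_cls.specificity_ci.lower, 6),
                               round(summary_cls.specificity_ci.upper, 6)],
        },
        "roc": {
            "auc": round(roc.auc, 6),
            "thresholds": [round(float(t), 6) for t in roc.thresholds],
            "sensitivity": [round(float(s), 6) for s in roc.sensitivity],
            "specificity": [round(float(s), 6) for s in roc.specificity],
        },
        "lead_times_months": {k: {kk: round(vv, 3) for kk, vv in v.items()} for k, v in sorted(leads.items())},
        "molecular_recurrence_months": {k: v for k, v in sorted(mol_times.items())},
        "transform_selected": transform.name,
        "transform_aic_sums": {k: round(v, 4) for k, v in aic_sums.items()},
        "regression": regress,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    roc_rows = ["threshold,sensitivity,specificity"] + [
        f"{t:g},{s:.6f},{p:.6f}"
        for t, s, p in zip(roc.thresholds, roc.sensitivity, roc.specificity)
    ]
    (out / "roc.csv").write_text("\n".join(roc_rows) + "\n")
    cio.write_run_manifest(out / "manifest.json", config.seed, dataclasses.asdict(config))
    return summary
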