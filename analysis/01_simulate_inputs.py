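#!/usr/bin/env python
"""Simulate the study's inputs: a rearranged tumor genome with paired-end
reads, a matched normal read set, and a 14 EM + 6 DF droplet-level plasma
cohort exported at file-demo scale.

Writes results/sim/: reference FASTA, tumor/normal FASTQ pairs, the planted
junction truth table (JSON), cohort and per-well quantification CSVs, and a
run manifest recording every parameter and seed.
"""

import json
from pathlib import Path

import ctdna_monitor as cm
from ctdna_monitor import io as cio

SEED = 20260101
OUT = Path("results/sim")
BULK = Path("scratch/sim")  # sequence-scale artifacts; regenerated on demand


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    BULK.mkdir(parents=True, exist_ok=True)

    genome = cm.make_toy_genome(3, 60_000, seed=SEED)
    events = cm.random_rearrangements(
        genome,
        ["translocation", "deletion", "inversion",
         "translocation", "deletion", "inversion"],
        seed=SEED + 1,
    )
    donor = cm.plant_rearrangements(genome, events)
    tumor = cm.simulate_read_pairs(donor.genome, 10.0, 100, 500.0, seed=SEED + 2)
    normal = cm.simulate_read_pairs(genome, 10.0, 100, 500.0, seed=SEED + 3, id_prefix="n")

    cio.write_fasta(genome, BULK / "reference.fa")
    cio.write_fastq_pair(tumor, BULK / "tumor_r1.fq", BULK / "tumor_r2.fq")
    cio.write_fastq_pair(normal, BULK / "normal_r1.fq", BULK / "normal_r2.fq")
    truth = [
        {
            "svtype": j.svtype, "chrom_a": j.chrom_a, "pos_a": j.pos_a,
            "strand_a": j.strand_a, "chrom_b": j.chrom_b, "pos_b": j.pos_b,
            "strand_b": j.strand_b,
        }
        for j in donor.junctions
    ]
    (OUT / "truth.json").write_text(json.dumps(truth, indent=1))

    # droplet-level cohort, exported at reduced per-well droplet counts so the
    # CSV stays a demo artifact; full-scale cohorts are generated in memory
    spec = cm.CohortSpec(seed=SEED + 4, droplets_mean=2_000.0, droplets_sd=0.0,
                         v_r=2_000.0 * 0.91e-3)
    cohort = cm.simulate_cohort(spec)
    records = cm.quantify_cohort(cohort)
    cio.cohort_table(records).to_csv(OUT / "cohort.csv", index=False)
    cio.quant_table(records).round(4).to_csv(BULK / "quant_demo.csv", index=False)
    cio.write_run_manifest(
        OUT / "manifest.json", SEED,
        {"genome": "3 x 60 kb", "coverage": 10.0, "read_length": 100,
         "insert_median": 500, "events": [e.svtype for e in events],
         "cohort": "14 EM + 6 DF, demo droplet scale 2000/well"},
    )
    print(f"planted {len(events)} events -> {len(donor.junctions)} junctions")
    print(f"tumor fragments: {len(tumor)}, normal fragments: {len(normal)}")
    print(f"cohort: {len(records)} patients, "
          f"{sum(len(r.samples) for r in records)} plasma samples -> {OUT} "
          f"(reads and per-well tables under {BULK})")


if __name__ == "__main__":
    main()
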