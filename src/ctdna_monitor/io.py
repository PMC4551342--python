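"""Readers/writers for the pipeline's interchange formats.

FASTA/FASTQ go through Biopython; tables are headered CSV via pandas; calls
are exported as BEDPE (0-based half-open, per the standard) with a JSON
sidecar for fusion sequences; copy-number tracks as bedGraph.  All writers
round-trip losslessly through the corresponding readers at toy scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .copynumber import CopyNumberTrack
from .droplets import DropletSet
from .genome import ToyGenome
from .reads import ReadPairSet
from .svcalls import RearrangementCall

CONTROL_TYPES = ("none", "positive", "negative", "ntc")
_ROLE_TO_CONTROL = {
    "sample": "none",
    "positive_control": "positive",
    "negative_control": "negative",
    "ntc": "ntc",
}
_CONTROL_TO_ROLE = {v: k for k, v in _ROLE_TO_CONTROL.items()}


# ------------------------------------------------------------------ FASTA/FASTQ


def write_fasta(genome: ToyGenome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> ToyGenome:
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not chroms:
        raise ValueError(f"no sequences in {path}")
    return ToyGenome(chroms)


def write_fastq_pair(reads: ReadPairSet, path_r1, path_r2) -> None:
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for r1, r2, frag_id in reads.pairs:
            f1.write(f"@{frag_id}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{frag_id}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq_pair(
    path_r1, path_r2, insert_median: float = 500.0, insert_spread: float = 50.0
) -> ReadPairSet:
    pairs = []
    read_length = 0
    for i, (rec1, rec2) in enumerate(
        zip(SeqIO.parse(str(path_r1), "fastq"), SeqIO.parse(str(path_r2), "fastq"))
    ):
        frag_id = rec1.id.rsplit("/", 1)[0]
        if rec2.id.rsplit("/", 1)[0] != frag_id:
            raise ValueError(f"record {i}: mate ids disagree ({rec1.id} vs {rec2.id})")
        pairs.append((str(rec1.seq).upper(), str(rec2.seq).upper(), frag_id))
        read_length = max(read_length, len(rec1.seq))
    return ReadPairSet(pairs, read_length, insert_median, insert_spread)


# ------------------------------------------------------------------ droplet CSV


def write_droplet_csv(wells: list[DropletSet], path) -> None:
    """Columns: assay_id, well_id, sample_id, control_type, raw_intensity."""
    frames = []
    for i, w in enumerate(wells):
        frames.append(
            pd.DataFrame(
                {
                    "assay_id": w.assay_id,
                    "well_id": f"well{i}",
                    "sample_id": w.sample_id,
                    "control_type": _ROLE_TO_CONTROL[w.role],
                    "raw_intensity": w.intensities,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_droplet_csv(path) -> list[DropletSet]:
    df = pd.read_csv(path)
    required = {"assay_id", "well_id", "sample_id", "control_type", "raw_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"droplet CSV missing columns: {sorted(missing)}")
    bad = set(df["control_type"].unique()) - set(CONTROL_TYPES)
    if bad:
        raise ValueError(f"unknown control_type value(s): {sorted(bad)}")
    wells = []
    for (_aid, wid, _sid, ctype), grp in df.groupby(
        ["assay_id", "well_id", "sample_id", "control_type"], sort=False
    ):
        wells.append(
            DropletSet(
                _aid, _sid, grp["raw_intensity"].to_numpy(float),
                role=_CONTROL_TO_ROLE[ctype],
            )
        )
    return wells


# ------------------------------------------------------------------ BEDPE / JSON


def write_bedpe(calls: list[RearrangementCall], path, sidecar_json=None) -> None:
    rows = []
    for i, c in enumerate(calls):
        rows.append(
            {
                "chrom1": c.chrom1,
                "start1": max(0, c.pos1 - c.ci_bp),
                "end1": c.pos1 + c.ci_bp + 1,
                "chrom2": c.chrom2,
                "start2": max(0, c.pos2 - c.ci_bp),
                "end2": c.pos2 + c.ci_bp + 1,
                "name": f"{c.svtype}_{i}",
                "support": c.n_supporting_fragments,
                "strand1": "+" if c.dir1 == "left" else "-",
                "strand2": "+" if c.dir2 == "right" else "-",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "support", "strand1", "strand2",
        ],
    ).to_csv(path, sep="\t", index=False, header=False)
    if sidecar_json is not None:
        side = [
            {
                "name": f"{c.svtype}_{i}",
                "svtype": c.svtype,
                "chrom1": c.chrom1, "pos1": c.pos1, "dir1": c.dir1,
                "chrom2": c.chrom2, "pos2": c.pos2, "dir2": c.dir2,
                "n_supporting_fragments": c.n_supporting_fragments,
                "split_read_support": c.split_read_support,
                "exact": c.exact,
                "ci_bp": c.ci_bp,
                "fusion_sequence": c.fusion_sequence,
                "flags": c.flags,
            }
            for i, c in enumerate(calls)
        ]
        Path(sidecar_json).write_text(json.dumps(side, indent=1))


def read_bedpe_sidecar(sidecar_json) -> list[RearrangementCall]:
    calls = []
    for d in json.loads(Path(sidecar_json).read_text()):
        calls.append(
            RearrangementCall(
                d["chrom1"], d["pos1"], d["dir1"], d["chrom2"], d["pos2"], d["dir2"],
                d["svtype"], d["n_supporting_fragments"], d["split_read_support"],
                d["fusion_sequence"], d["ci_bp"], d["exact"], list(d["flags"]),
            )
        )
    return calls


def write_bedgraph(track: CopyNumberTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, ratios in track.log2_ratio.items():
            for i, r in enumerate(ratios):
                val = "nan" if np.isnan(r) else f"{r:.4f}"
                fh.write(f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{val}\n")


# ------------------------------------------------------------------ tables


def quant_table(records) -> pd.DataFrame:
    """Per-sample quantification table from monitoring PatientRecords."""
    rows = []
    for rec in records:
        for s in rec.samples:
            for assay, q in {**s.rearr_quant, "control": s.control_quant}.items():
                rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "sample_time_months": s.time_months,
                        "assay_id": assay,
                        "P": q.P,
                        "T": q.T,
                        "lambda": q.lam,
                        "c_vi": q.c_vi,
                        "copies_per_reaction": q.copies_per_reaction,
                        "copies_per_ml_plasma": q.copies_per_ml_plasma,
                        "saturated": q.saturated,
                        "ctdna_percent": s.ctdna_percent,
                        "sample_positive": s.positive,
                    }
                )
    return pd.DataFrame(rows)


def cohort_table(records) -> pd.DataFrame:
    """Per-patient clinical table (one row per patient)."""
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "group": rec.group,
            "time_to_recurrence_months": rec.time_to_recurrence,
            "time_to_last_followup_months": rec.time_to_last_followup,
            "death": rec.death,
            "sample_times_months": ";".join(f"{s.time_months:g}" for s in rec.samples),
        }
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_run_manifest(path, seed: int, params: dict) -> None:
    Path(path).write_text(json.dumps({"seed": seed, "params": params}, indent=1, sort_keys=True, default=str))
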