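# ctdna-monitor

Tools for studying **circulating tumor DNA (ctDNA) monitoring** after primary
breast cancer surgery: whether serial blood-plasma measurements of
tumor-specific chromosomal rearrangements can discriminate patients who go on
to develop clinical metastasis (EM, eventual-metastatic) from patients with
long-term disease-free survival (DF), and how far molecular detection leads
clinical detection.

The package is aimed at computational biologists and biostatisticians who
want a fully synthetic, end-to-end testbed for rearrangement-fingerprint
liquid-biopsy pipelines: every stage — tumor sequencing, droplet digital PCR
(ddPCR), classification, regression — runs on generated data with known
ground truth.

## What it computes

**Rearrangement calling.** Somatic junctions (translocations `t`, deletions
`del`, inversions `inv`) are detected from paired-end reads by the classic
two-signal scan: *discordant pairs* (mates on different chromosomes, an
implied fragment length far outside the library distribution, or inconsistent
orientation) are clustered per junction side; calls require ≥ 2 supporting
fragments; *split reads* spanning the junction refine breakpoints to base
precision and let the fusion sequence be reconstructed from reference flanks.
Calls seen in matched normal reads are removed as germline. A binned
read-depth track (log2 ratio vs the genome-wide median) summarizes copy
number, and monitoring candidates are selected across the range of
supporting-read counts.

**ddPCR quantification.** Droplet fluorescence is normalized per assay to a
0–1 scale anchored on the negative-control median (→ 0) and the
positive-control positive-cluster median (→ 1); droplets with relative
intensity ≥ 0.5 are positive. With `P` positive of `T` droplets, droplet
volume `V_d = 0.91e-3` µl, reaction volume `V_r` and input volume `V_i`,
the concentration per µl input circulating DNA is

```
λ = −ln(1 − P/T),    C_Vi = λ · V_r / (V_d · V_i)
```

Replicate wells are pooled by summing droplet counts. Concentrations convert
to copies per ml plasma via the plasma volume represented by the input
(20 µl per reaction by default).

**Monitoring.** A plasma sample is ctDNA-positive when any rearrangement has
a molecular count > 0; its ctDNA level is the maximal rearrangement
concentration as a percentage of the 2p14 total-cfDNA control. A patient is
recurrence-positive when any strictly post-surgery sample is positive.
Sensitivity `TP/(TP+FN)` and specificity `TN/(TN+FP)` carry Clopper–Pearson
exact intervals (one-sided when the estimate is 1); a threshold sweep over
the normalized intensity scale re-calls every droplet and yields a ROC curve
with the AUC integrated over the monotone hull.

**Outcome regression.** Because ctDNA level separates the outcome groups
almost perfectly, odds ratios come from **Firth-penalized** logistic
regression (finite estimates under separation), with the covariate transform
(identity / log2-with-floor / sqrt) chosen by summed AIC over the recurrence
and death models. With the log2 transform, `exp(β₁)` is the odds ratio per
doubling of ctDNA level.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```
$ python analysis/01_simulate_inputs.py
planted 6 events -> 8 junctions
tumor fragments: 14488, normal fragments: 9093
cohort: 20 patients, 99 plasma samples -> results/sim (reads and per-well tables under scratch/sim)

$ python analysis/02_call_rearrangements.py
8 somatic calls (0 germline-filtered)
planted junctions recovered at base precision: 8/8
candidates selected for monitoring (k=5): [('inv', 32), ('del', 26), ('t', 23), ('inv', 21), ('inv', 20)]

$ python analysis/03_ddpcr_validation.py
admixture linearity: slope 1.009, R^2 0.9993 over 13 points
limit of detection: 0.0122% tumor content detected in >=95% of 100 replicates (~7.4 copies per reaction)

$ python analysis/04_cohort_monitoring.py
classification: sensitivity 1.00 (0.81-1.00), specificity 1.00 (lower bound 0.61)
ROC AUC over 21 thresholds: 1.000
lead time: mean 16.1 months (range 0-41) for 14/14 EM patients

$ python analysis/05_outcome_regression.py
covariate transform by summed AIC: log2
  recurrence: OR 1.44 per doubling (profile 95% CI 1.13-2.44; Wald p 0.029)
  death: OR 1.14 per doubling (profile 95% CI 0.96-1.40; Wald p 0.191)
recovery: generating OR 2.0 -> mean fitted OR 2.008 over 200 cohorts of n=500
```

Reading the output: all 6 planted rearrangements (8 novel junctions —
inversions create two each) are recovered with exact breakpoints and zero
false calls on the matched normal; the simulated assay is linear on log–log
axes down to ~7 target molecules per reaction; on this cohort every EM
patient had a positive follow-up sample before clinical recurrence (a mean
lead of 16 months), no DF patient ever tested positive, and the fitted odds
of recurrence rise ~1.4-fold per doubling of ctDNA level.

A single `ctdna` CLI wraps the same stages (`ctdna run`, `ctdna simulate`,
`ctdna call`, `ctdna quantify`, `ctdna monitor`, `ctdna regress`); try
`ctdna run --seed 1 --out report/`.

## Layout

- `src/ctdna_monitor/` — the library: `genome`/`reads`/`droplets`/`cohort`
  (synthetic data), `align`/`svcalls`/`copynumber`/`caller` (rearrangement
  calling), `quant`/`lod` (ddPCR), `monitoring`, `stats`, `io`, `pipeline`,
  `cli`.
- `analysis/` — the numbered study drivers shown above.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
- `scratch/` — regenerable bulky artifacts (FASTQ/FASTA); not tracked.
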