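# Methods

This note records the models behind `ctdna_monitor`, the defaults and why
they were chosen, and what the synthetic experiments can and cannot say
about real data.

## Synthetic data model

### Toy genomes and rearrangements

Reference chromosomes are i.i.d. uniform A/C/G/T, which makes a 21-mer
unique with overwhelming probability and lets an exact-seed aligner stand in
for a production aligner at the 10⁵-bp scale. Somatic events are planted as:

- **translocation** — a derivative contig `chrA[:a] + chrB[b:]` is added and
  the intact homologues are retained (a tumor keeps normal copies);
- **deletion / inversion** — the chromosome is rewritten in place; an
  inversion creates two novel junctions (left and right edge of the
  reverse-complemented segment), both carried in the truth table.

Breakpoints are resampled until every novel junction has **zero
micro-homology** between its flanks. Without this, the breakpoint is only
defined up to the homology tract and "exact recovery" is ill-posed; the
resampling (accepting ~56% of candidate sites) makes base-precision recovery
a well-defined target. Real junctions frequently do carry micro-homology, so
the planted-truth experiments measure the machinery, not breakpoint
ambiguity in real tumors.

### Read pairs

Fragments are uniform along the genome, log-normal in length around a
median insert of 500 bp (log-SD 0.1, i.e. SD ≈ 50 bp; only the median is an
observable constraint, the spread is a package choice), sequenced
convergently from both ends at a configured read length (default 100 bp).
The fragment count is Poisson with mean `coverage × G / (2 × read_length)`.
Base-call errors are i.i.d. substitutions from a dedicated RNG stream, so
fragment coordinates are reproducible across error rates at a fixed seed.
No GC bias, no indels, no quality scores, no chimeras.

### Droplets

`N` target molecules are partitioned uniformly at random over `T` droplets
(multinomial occupancy; Poisson per droplet in the large-`T` limit). A
droplet draws its fluorescence from a positive Gaussian component iff it
holds ≥ 1 amplifiable target after optional per-copy false-negative
thinning, else from the negative component. Defaults (RFU):
µ₋ = 1000, σ₋ = 30, µ₊ = 9000, σ₊ = 200, with `T ~ Normal(25 704, 2 320)`
per well. The components are ≈ 13 σ₋ apart at the 0.05 grid point of the
normalized scale, so the negative cloud cannot cross any positive calling
threshold in double precision: this is the "no false-positive mechanism"
default, chosen because junction assays read out cleanly bimodal signals
and control material yields zero positives at the million-droplet scale.
An optional `rain_fraction` mixes in uniform intermediate intensities for
robustness experiments.

Droplet volume is 0.91 nl. Note 25 704 × 0.91 nl ≈ 23.4 µl exceeds the
default 20 µl reaction volume; the generator therefore draws the copies
*among analyzed droplets* as Poisson with mean `C_rxn · T·V_d/V_r`, which
makes the Poisson-corrected estimator unbiased by construction. Scaled-down
test cohorts instead set `V_r = T·V_d` so all reaction contents are
analyzed and detection behaviour is preserved at lower droplet counts.

### Plasma cohort

14 EM + 6 DF patients. Each has a presurgical sample (month 0) and
follow-up samples at months {12, 24, 36} plus an optional subset of {4, 8}
(4–6 samples total, mirroring a 3–8/12/24/36-month protocol). Total
cell-free DNA per patient is log-normal with median 1 450 copies/ml plasma
(log-SD 0.75; mean ≈ 1 900, range ≈ 300–9 000) with per-sample log-normal
jitter (SD 0.3) — calibrated to the scale a copy-number-stable control
assay reports in plasma.

EM kinetics are an **exponential-growth trajectory after a latent onset**:
the tumor fraction of cfDNA is 0 before onset `t₀ ~ U(6, 26)` months, then
`f(t) = min(0.7, f₀ · 2^((t−t₀)/T_d))` with `f₀ = 0.5%` and doubling time
`T_d = 3` months. Clinical recurrence is `U(14, 61)` months. This is a
stand-in: the underlying study design shows trajectories but does not
parameterize inter-sample kinetics, so onset/doubling are package choices
tuned only to produce ctDNA fractions in the observed 0.5–70% range.
4–6 rearrangement assays per patient receive Dirichlet shares of the
signal; with probability 0.25 an assay is absent from the metastatic clone
(share 0). DF patients have identically zero tumor-target copies at every
post-surgery time-point — specificity failures can therefore only come
from the droplet model, and the default model has none. Presurgical
positivity occurs in ~30% of EM patients at a 0.2–2% fraction, and never
in DF patients.

Because every EM patient samples at 24 and 36 months and onset is ≤ 26
months, detection is expected for essentially all EM patients; occasional
misses (low-baseline patients with late onset) reproduce the realistic
13/14-type sensitivity rather than being a failure mode.

## ddPCR analytics

Normalization anchors: negative anchor = median of the negative-control
well; positive anchor = median of positive-control droplets above the
valley between its two modes, found by a 1-D two-cluster median iteration
(parameter-free, robust to rain and outliers; the anchor statistic is a
package decision). The affine map is invertible and recorded. Assays whose
anchors do not separate are rejected as uninterpretable.

Positive calling is inclusive (`rel ≥ threshold`, default 0.5). Pooling of
replicate wells sums `(P, T)` rather than averaging concentrations — at
single-digit copy numbers the summed counts keep the Poisson statistics
exact, whereas averaging would discard information; whether the original
workflow pooled or averaged is not stated, so pooling is declared here.
Saturation (`P = T`) flags the result as above the quantifiable range, with
a continuity-corrected bound (`P = T − 0.5`) available as an option.
`V_r` defaults to 20 µl (named but not valued in the source protocol);
`V_i` = 4 µl corresponding to 20 µl plasma (0.020 ml plasma-equivalent).

Dilution linearity fits OLS on log10–log10 axes after dropping non-positive
measurements (with a count), matching how admixture series are displayed
and summarized (slope, intercept, R²).

## Limit-of-detection experiment

The admixture series is twofold from 50% tumor content down through
50/2¹² ≈ 0.0122% (labelled 0.01%), with total input fixed at 200 ng =
~60 600 haploid genomes at 3.3 pg each. The copy number loaded into a well
is Poisson around `fraction × total` — the aliquot sampling that actually
limits detection at the bottom of the series (≈ 7.4 expected copies at the
final member, detection probability `1 − e^(−7.4) ≈ 0.9994`). Each
replicate runs the full droplet → normalize → call path; the LOD is the
smallest fraction detected (≥ 1 positive droplet) in ≥ 95% of replicates.

## Classification, ROC and time summaries

Follow-up means strictly post-surgery (`t > 0`); presurgical samples are
reported separately and never enter classification. Clopper–Pearson
intervals use beta quantiles; proportions estimated at 1 get a one-sided
95% lower bound, others two-sided 95%. The ROC grid defaults to step 0.05
on [0, 1] — finer than a 0.1 grid so that plateaus of equivalent optimal
thresholds are resolved — and the AUC is the trapezoidal area under the
monotone (staircase) hull of the swept operating points with (0,0) and
(1,1) appended; refining the grid can only raise this hull. Lead time is
clamped at zero (molecular detection after clinical detection gains
nothing) with the raw signed difference preserved for auditing.

## Firth-penalized regression

The penalized likelihood `l*(β) = l(β) + ½ log det I(β)` is maximized by
Newton iteration on the modified score
`U*_r = Σᵢ [yᵢ − πᵢ + hᵢ(½ − πᵢ)] x_ir` with step-halving (≤ 10 per step)
on non-increase of `l*`; convergence is `max|U*| < 1e−8` within 50
iterations. Standard errors come from the inverse penalized information;
Wald tests from `z = β/SE`. Profile-penalized-likelihood intervals are
available because Wald intervals cannot produce half-infinite bounds of
the kind that arise under near-separation; profile bounds that never cross
the χ² cutoff are reported infinite. On any 2×2 design the fit equals the
add-½-to-each-cell closed form (tested to 6 decimals), and a brute-force
grid maximization of `l*` cross-checks the optimizer.

Covariate construction: per patient, the most recent post-surgery sample
at or before the event/censoring time, represented by its
maximal-percentage rearrangement. Zeros are floored at 0.01% before log2 —
the assay's demonstrated discrimination limit; the flooring rule is a
package decision surfaced as a parameter, since undetectable samples must
receive a finite log2 value. AIC uses the maximized *penalized*
log-likelihood (`AIC = −2l* + 2k`), a convention choice consistent with
selecting among Firth fits; the transform minimizing the summed AIC over
the recurrence and death models is selected, ties breaking to the earlier
candidate.

## Problem sizes and numerical choices

Planted-truth experiments use 3 × 60 kb genomes, 6 events, 10× error-free
coverage (k = 21 seeds, unique-match anchoring, multi-mapping reads
excluded; mismatch-tolerant placement only for full-length reads).
Monte-Carlo checks use 1 000 replicates for occupancy/estimator
consistency, 100 replicates per admixture fraction, 500 cohorts of n = 500
for odds-ratio recovery, and 20 seeds for cohort-level ROC behaviour; these
sizes give Monte-Carlo errors comfortably inside the asserted bounds.
Breakpoint votes tie-break to the most frequent, then smallest coordinate;
candidate selection tie-breaks by split-read support, then lexicographic
breakpoint order — all determinism choices. Clustering windows default to
the median insert size; pair discordance uses median ± 4 SD of the
realized fragment-length distribution.

## Limitations

- The aligner is exact-seed and toy-scale: no indels, no base qualities, no
  mappability model; real pipelines face repeat-driven ambiguity the
  uniform-base genome deliberately lacks.
- The droplet model has no rain by default and no false-positive channel;
  assays with chemistry-driven rain would need the mixture option and a
  calibrated threshold.
- ctDNA kinetics between sampling points are an assumed exponential model,
  not an inference about any patient population; lead-time distributions
  from the synthetic cohort characterize the pipeline, not the disease.
- Passing synthetic-cohort tests demonstrates correctness of the
  computation under the stated generative model — not clinical performance
  on real plasma, where extraction efficiency, fragmentation and storage
  effects enter upstream of everything modelled here.
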