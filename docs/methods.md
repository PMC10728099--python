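# Methods

## The assay and its computational model

`linemeth` models a targeted bisulfite amplicon assay that reads genomic
hypomethylation from ten probes against evolutionarily young LINE-1
elements. LINE-1 methylation tracks genome-wide methylation loss, which
in turn associates with resistance to immune checkpoint blockade (ICB);
the computational question is how to turn amplicon reads into a
per-sample methylation score, and that score into a survival and
response predictor, when the specimen may be tissue (confounded by tumor
purity) or cell-free DNA (cfDNA).

Each probe is abstracted as a single consensus amplicon. The real
targets map to roughly 2000 genomic LINE-1 copies, but the pipeline's
arithmetic operates per probe, so nothing downstream needs a genome.
Resolving methylation at 0.5% granularity over ~2000 loci motivates the
assay's read budget of (1/0.005) x 2000 = 400,000 reads per sample
(`required_reads`).

## Read-level quantification

**Assignment.** Reads are assigned to (probe, strand) by gapped edit
distance (edlib) against each probe reference, with bisulfite-consistent
substitutions declared equal: read T matches reference C in the Watson
orientation, read A matches reference G in the reverse-complemented
Crick orientation. Both the read and its reverse complement are tried
against all probes; the minimum-distance combination wins, ties across
probes are left unassigned, and reads whose best distance exceeds 10% of
their length (or shorter than 30 nt) are dropped.

**Strand chemistry.** In Watson coordinates a Watson read shows a scored
cytosine as C (methylated) or T (converted). A Crick read shows
methylation at the CpG's *paired guanine* (offset + 1) as G or A — the
target cytosine position itself always reads C on a Crick read, so
scoring it there would be circular. CpA sites are asymmetric (the
complementary strand carries TpG) and are scored from Watson reads
only. The same geometry yields Crick-strand conversion observations at
Watson G positions outside Crick CpG/CpA context.

**Indel filter.** Reads with an insertion or deletion inside the target
region padded by ±30 nt are removed before counting.

**Beta value.** Per probe, methylated (M) and converted (U) observations
are pooled over all scored sites and both strands (depth-weighted, which
is what per-probe transition counting amounts to), then

    beta = M / (U + M) x sample_conversion_rate

clipped to [0, 1]. The sample conversion rate is the unweighted mean of
per-position conversion fractions over naive cytosines — cytosines
outside CpG/CpA context, assumed unmethylated; the bundled panel
annotates 92 of them. Because methylated cytosines resist conversion, an
incompletely converted sample inflates M; multiplying by the conversion
rate is the assay's first-order correction. Under the measurement model
the recovered beta for true methylation m and conversion c is
(m + (1−m)(1−c))·c, which the test suite uses as a closed-form oracle.

Probes with fewer than `min_depth` reads (default 100) or M+U = 0 report
a missing beta. The default scoring context is CpG+CpA on probes that
annotate CpA targets (P8–P10) and CpG elsewhere; a global `cpg_only`
switch exists for comparability with array platforms, which only see CpG
signal.

## Imputation

Samples missing P8–P10 are completed by per-probe ordinary least squares
on P1–P7 with intercept, trained on complete cases (at least 9 required,
i.e. more rows than parameters). Predictions are clipped to [0, 1] and
flagged. No regularization: the seven predictors are strongly
correlated with the response by construction, and the training cohorts
of interest are an order of magnitude larger than the design.

## Probe weighting

Candidate weight vectors come from simulated probe sets: a set of size s
drawn uniformly *with replacement* (a probe can be picked several times)
from the ten probes; each probe's weight is its count divided by s, an
exact rational summing to one. The default search uses set sizes
(10, 15, 20, 30, 50, 75, 100, 150, 200, 300) x 5000 iterations = 50,000
candidates from one seeded generator.

Each candidate is evaluated on a training cohort by mean-splitting its
weighted score and computing the signed log-rank P (below). Performance
ranks candidates by significance in the hypothesized direction
(methylation-high surviving better): the selection maximizes
sign x (1 − p), so a small positive signed P is best and a strongly
significant *reversed* split is worst. A plain "most extreme signed
value" rule was rejected because any negative value would sort below
every positive one, letting chance reversed-direction candidates win on
cohorts with a genuine positive effect. Ties break to the earliest
candidate. Trained weights are applied to other cohorts through
`apply_weights`, which only consumes a finished vector — cross-cohort
application cannot refit.

## Survival evaluation

Cohorts are stratified at the cohort mean of the methylation score
(ties at the mean go to "low"; a constant score is a degenerate split
and an error). Groups are compared with the two-group log-rank test
(1-df chi-square approximation, as in standard survival packages); the
implementation is cross-checked in the tests against lifelines and
against an exhaustive permutation oracle at small n. The Kaplan–Meier
estimator is lifelines' product-limit fit.

The **signed P** convention attaches direction to the log-rank P: +p
when the methylation-high group survives better, −p otherwise. The sign
comes from the high group's observed-minus-expected events (O−E < 0
means better survival); O−E = 0 takes +1 by convention, a tie-free,
statistic-internal criterion.

**Bootstrap.** Each of R resamples (1000 or 5000) draws n patients with
replacement — keeping each patient's (score, time, event) triple intact —
and recomputes the mean-split signed P. Degenerate resamples (constant
scores, empty group, zero events) are redrawn and counted, so the output
always has length R and is pairable across predictors. Two predictors
bootstrapped with the same seed share resampled patient sets, which is
what justifies comparing their signed-P distributions with the paired
two-sided Wilcoxon signed-rank test (all-zero differences return P = 1
under the zero-drop rule).

A caution established during development: the bootstrap distribution of
a *single* cohort centers on that cohort's empirical association, not on
zero, so even under a true null its sign balance is essentially a draw
from a uniform distribution. Null calibration of the signed-P machinery
therefore pools bootstrap runs over independent null cohorts; the test
suite does exactly that.

## Response prediction

Per-probe sample SDs (n−1 denominator) drive probe selection: the
argmin-SD probe is always dropped (first index on ties) along with every
probe below 0.015 — probes that barely vary cannot separate classes. The
kept betas enter a binomial GLM (logit link; identity-link Gaussian
available for sensitivity) of durable-clinical-benefit status, evaluated
in-sample by ROC-AUC computed as the Mann–Whitney rank statistic with
half credit for ties. Perfect separation is flagged but the monotone
scores are still returned and ranked. Evaluation is in-sample by
default; no cross-validation.

## Longitudinal monitoring

Paired deltas are later − baseline per probe, inner-joined on patient,
so progressive hypomethylation is negative; the per-probe one-sided
one-sample t-test asks whether deltas fall below zero (zero-variance
probes degenerate to P = 0.5/0/1 by the sign of the common delta).
Direction counts use strict signs with zeros reported separately. Named
subsets FIVE_PROBE = {P2, P3, P5, P8, P9} and FOUR_PROBE = {P2, P3, P8,
P9} give tumor-burden-sensitive averages; monitoring reports *both* the
subset deltas and the all-probe absolute averages, because the subset
tracks progression while the all-probe average is the better survival
predictor — the report never silently chooses.

## Synthetic data

**Cohort generator.** A two-component mixture formalizes the purity
argument: per patient, true tumor methylation m (one value per probe),
tissue beta = p·m + (1−p)·normal and cfDNA beta = f·m + (1−f)·normal,
with tumor purity p and ctDNA fraction f drawn independently — tissue
betas are purity-confounded by construction, cfDNA betas are not, and
PBMC betas sit at the normal level. Defaults, chosen once as realistic
study conditions:

| parameter | default | rationale |
|---|---|---|
| normal/PBMC level | 0.80 | non-malignant LINE-1 methylation is invariably high |
| per-probe tumor Beta means | 0.52–0.65, concentration 30 | hypomethylating tumors sit well below normal with ~0.09 SD |
| probe correlation (Gaussian copula) | 0.8 | genome-wide hypomethylation moves all LINE-1 copies together |
| purity p | Uniform(0.1, 0.9) | biopsy purity varies widely |
| ctDNA fraction f | Uniform(0.2, 0.5), independent of p | moderate plasma tumor content in advanced disease |
| hazard slope γ | 8 per unit mean methylation | hazard ratio ≈ 2.5 across the methylation IQR, typical of ICB responder contrasts |
| baseline hazard | 1/500 per day; censoring hazard ratio 0.4 | median survival near one year, ~30% censoring |
| measurement depth | 5000 reads/probe (binomial noise) | reuses the read-level model rather than ad hoc Gaussian noise |

Survival is exponential with hazard h = h0·exp(−γ·(m̄ − mean(m̄)));
responder (DCB) status is a noisy threshold on mean tumor methylation.
`simulate_progression_pair` adds a matched later timepoint with tumor
methylation drifted down and ctDNA fraction up.

**Read generator.** Per read: strand uniform; scored cytosines stay C
(Watson) or keep the paired G (Crick) with probability m, otherwise
convert with the conversion probability; all other cytosines (guanines
on Crick) convert as unmethylated; optional 1–2 nt deletions at a
per-read indel rate; Crick reads are emitted reverse-complemented. A
truth sidecar records every read's probe, strand and indel status.

What the generators deliberately do not emulate: fragmentomics, GC or
PCR bias, sequencing substitution errors, per-genomic-copy heterogeneity,
clonal evolution, and non-exponential survival. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and the qualitative
purity/cfDNA structure, not performance on real patient data.

## Problem sizes and numerical choices

The test suite runs read-level recovery at 10,000 reads per probe on a
two-probe panel, cohort experiments at 100–200 patients with 1000
bootstrap resamples, and the candidate-pool check at the full 50,000
vectors; these sizes keep binomial standard errors a factor of 3–10
below the asserted tolerances. Betas are clipped to [0, 1] (the
conversion correction can only shrink, so clipping matters only for
pathological inputs, and rates above 1 are rejected). Log-rank variance
zero (no information) returns chi-square 0, P 1. RNG throughout is
numpy's PCG64 with explicit seeds recorded in outputs.

## Known limitations

In-sample AUC overstates generalization; the weighting search explores
random candidates rather than optimizing; the amplicon consensus model
cannot express copy-to-copy methylation differences; the conversion
correction is first-order (it rescales rather than deconvolves
conversion failure); and imputation is single-value OLS without
uncertainty propagation.
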