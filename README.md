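# linemeth

Targeted LINE-1 bisulfite amplicon methylation quantification and
ICB-response biomarker evaluation.

Genome-wide hypomethylation — conveniently read out from young LINE-1
repeats — associates with resistance to immune checkpoint blockade
(ICB). Measuring it from tissue is confounded by tumor purity: the
hypomethylated tumor signal is diluted by normal cells, so low-purity
biopsies overestimate methylation. Cell-free DNA (cfDNA) offers a
noninvasive readout whose tumor content is independent of biopsy purity.
`linemeth` implements the complete computational pipeline for such an
assay, for bioinformaticians and translational researchers who want to
quantify LINE-1 methylation from bisulfite amplicon reads and evaluate
it as a survival/response biomarker — plus a synthetic-data generator so
every stage is testable without patient data.

## What it computes

**Beta values.** Reads are assigned to the ten amplicon probes by
bisulfite-tolerant alignment, strand-separated (C→T transitions on the
Watson strand, G→A on the Crick strand), filtered for indels near the
target region (±30 nt), and tallied into methylated (M) and converted
(U) counts. Per probe,

    beta = M / (U + M) × sample_conversion_rate

where the conversion rate is estimated from 92 naive (non-CpG/CpA)
cytosines across the panel. Missing P8–P10 betas can be imputed by OLS
on P1–P7.

**Biomarker evaluation.** Cohorts are stratified at the mean of a
(possibly probe-weighted) methylation score and compared by the log-rank
test with a signed-P convention: +P when the methylation-high group
survives better, −P otherwise. Robustness comes from bootstrap
resampling (1000/5000 resamples); predictors are compared by paired
Wilcoxon signed-rank on their signed-P distributions. Probe weights are
searched over 50,000 randomized candidate vectors (counts/set-size from
simulated probe sets of sizes 10–300, 5000 iterations each). Response
classification drops low-SD probes (< 0.015, plus the smallest), fits a
binomial GLM, and reports ROC-AUC. Longitudinal monitoring computes
paired per-probe deltas between timepoints and one-sided hypomethylation
tests.

See `docs/methods.md` for the full model description and the synthetic
generator's assumptions.

## Worked example

Simulate a 60-patient cohort (tissue + cfDNA + PBMC betas with known
truth), then evaluate cfDNA methylation as a survival and response
predictor:

```sh
linemeth simulate cohort --n 60 --seed 3 --out cohort/
linemeth survival run --beta cohort/cfdna_beta.tsv --clinical cohort/clinical.csv \
    --resamples 200 --seed 1
linemeth predict auc --beta cohort/cfdna_beta.tsv --clinical cohort/clinical.csv
```

prints

```
signed P = 0.1556 (ns), chi2 = 2.016
bootstrap: median signed P = 0.08499 over 200 resamples (0 redrawn)
kept probes: P1, P2, P3, P4, P5, P7, P8, P9, P10
ROC-AUC = 0.905
```

The point-estimate split on this small cohort is not significant
(signed P = +0.16; the positive sign says the methylation-high group
survived better, matching the hypomethylation-resistance hypothesis),
and the bootstrap median (+0.085) shows the direction is stable across
resamples. The GLM on the nine variable probes separates responders
from non-responders with AUC 0.905 in-sample.

Read-level quantification round-trips through the same machinery:

```sh
linemeth simulate reads --m 0.7 --conversion 0.99 --depth 30 --seed 2 --out sim.fastq
linemeth quant run --fastq sim.fastq --out beta.tsv --sample-id demo --min-depth 10
```

```
wrote 300 reads to sim.fastq
demo: assigned=300 unassigned=0 indel_removed=0 conversion=0.9913
```

and the resulting `beta.tsv` row holds per-probe betas near the
simulated truth of (0.7 + 0.3·0.01)·0.99 ≈ 0.696 (e.g. P1 0.687, P2
0.699 at this shallow depth), plus the estimated conversion rate and
per-probe depths.

The same operations are available as library calls
(`linemeth.quantify_sample`, `linemeth.bootstrap_signed_p`,
`linemeth.prediction_auc`, ...), which is the recommended interface for
anything beyond one-off runs.

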