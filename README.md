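# glioma-omics

Integrated tumor/normal multi-omics analysis for exome, methylation-array
and RNA-seq derived data, built around the workflow used to characterize
diffuse gliomas: copy-number segmentation with tumor-purity estimation
from allelic imbalance, purity-adjusted somatic-variant filtering,
Infinium-style methylation clustering and differential-promoter analysis,
fusion-junction filtering, and the accompanying statistics (Fisher exact,
Welch *t* + Benjamini–Hochberg, Wilcoxon rank-sum, Kaplan–Meier and
log-rank) implemented natively. Every stage is exercisable on seeded
synthetic data with known ground truth, so the whole pipeline is testable
without any external cohort.

## Who this is for

Researchers who need a transparent, auditable reimplementation of the
tumor/normal exome + 450K/EPIC methylation + RNA-seq analysis stack —
either to reproduce this style of study on their own cohorts or to use
the synthetic generators as a benchmark harness for individual stages.

## The models at the core

**Copy number and purity.** For a specimen with tumor-cell fraction
α and a region at integer copy number *n*, the expected tumor/normal
depth ratio is

    r(n) = (2(1 − α) + n·α) / 2

Read depths per capture region are library-size normalized, GC-corrected
(40 GC bins, divide by bin median) and smoothed (centered moving average,
window 5). Candidate ratio peaks come from a Mexican-hat continuous
wavelet transform of the ratio density, refined by 1-D Gaussian-mixture
EM; a hidden Markov model with those Gaussian emissions (stay probability
1 − τ, τ = 1e-4) assigns regions to states by Viterbi. Heterozygous-SNP
mirrored B-allele fractions classify segments: for a hemizygous-deletion
LOH segment m = 1/(2 − α), for copy-neutral LOH m = (1 + α)/2, giving the
purity inversions α = 2 − 1/m and α = 2m − 1. A joint lattice fit over
candidate purities (ratio residuals of segment means plus an
allelic-imbalance consistency term) produces the final α and integer copy
numbers; when no allelic or VAF information exists, α defaults to 0.2.

**Somatic filtering.** Candidates pass a tumor-vs-normal Fisher exact
test (p < 0.01, normal VAF ≤ 0.03), heuristic artifact filters (depth,
alt-read support, strand-bias binomial test, homopolymer-adjacent
indels), and the purity-adjusted VAF rule: vaf/α ≥ 15% is retained.

**Methylation.** Beta = M/(U + M + 100). After removing X/Y and
SNP-associated probes and intersecting platforms, the top-8000-SD probes
feed consensus k-means (k = 6, 10 random starts, 1000 iterations,
resampled 100×), with final labels from an average-linkage cut of
1 − consensus. Promoter methylation is the mean beta of probes within
±1500 bp of the TSS; differential promoters use Welch *t* with BH
q-values and are called at q < 0.01 and |Δβ| > 0.2. Samples stratify by
an anchor promoter at beta 0.5/0.7; distal probes (>1500 bp from any
TSS) hypomethylated at q < 1e−10 and Δβ < −0.25 are exported as 1 kb BED
windows for motif discovery.

**Expression and fusions.** FPKM on the longest isoform; gene-set
enrichment via the weighted Kolmogorov–Smirnov running sum with a
gene-set permutation null (NES, FDR q). Fusion candidates survive only
with ≥12 bases matched on both sides of the junction in each read, more
than four spanning reads, and ≥100 kb between same-chromosome
breakpoints.

## Worked example

The end-to-end synthetic pipeline (simulate → copy number/purity →
somatic filter → methylation clustering → fusion filter):

```bash
glioma-omics run --alpha 0.5 --seed 7 --out runs/demo
```

prints

```json
{
  "seed": 7,
  "alpha_simulated": 0.5,
  "alpha_estimated": 0.49,
  "purity_method": "loh_allelic_imbalance",
  "n_segments": 11,
  "n_variants_pass": 200,
  "n_meth_clusters": 6,
  "n_fusions_called": 3,
  "n_fusions_true": 3
}
```

— the genome was simulated at purity 0.50 and the engine recovered 0.49
from LOH allelic imbalance; all 200 planted somatic variants pass the
filters while every planted artifact is removed; the six planted
methylation subtypes and all three true fusions (among 20 decoys) are
recovered. The numbered drivers under `analysis/` run the same stages as
a narrative study (simulation, copy number, somatic filtering,
methylation, expression/fusions, survival) and write their tables under
`results/`. Each subcommand (`simulate`, `purity-cna`, `somatic-filter`,
`meth-cluster`, `meth-diff`, `meth-stratify`, `meth-distal`,
`fusion-filter`, `gsea`) is also available standalone; see
`glioma-omics --help`.

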