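# Methods

This note documents the models, the defaults and why they were chosen,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## Statistical primitives

All hypothesis tests are implemented natively in `glioma_omics.stats`;
only special functions (log-gamma, the *t*/normal/chi-square distribution
functions) come from `scipy.special`. Conventions:

- **Fisher exact (2×2), two-sided** by the point-probability rule: the
  p-value sums hypergeometric probabilities of all tables sharing the
  margins whose probability is ≤ that of the observed table, with a
  relative tie tolerance of 1e-7 so floating-point noise cannot exclude
  genuinely tied tables. This is the convention of R's `fisher.test` and
  reproduces the published two-sided values for the mutation-frequency
  comparisons.
- **Welch *t*** with Welch–Satterthwaite degrees of freedom; when both
  group variances vanish the p-value is 1 for equal means and 0
  otherwise. A vectorized row-wise variant backs the per-gene and
  per-probe screens.
- **Benjamini–Hochberg** step-up, order-preserving, clipped at 1.
- **Wilcoxon rank-sum** with midrank ties; exact enumeration of all
  C(n, n_a) assignments when the combined n ≤ 12 (matching the scale of
  the expression comparisons, 14 vs 8), otherwise a tie-corrected normal
  approximation with 0.5 continuity correction. Exact and approximate
  paths agree within 0.05 absolute on small samples.
- **Kaplan–Meier** product limit; **log-rank** in the unweighted
  (Mantel–Haenszel) form with the hypergeometric variance.

## Copy number and purity

The two-population read mixture gives the expected tumor/normal depth
ratio r(n) = (2(1−α) + nα)/2 for tumor purity α and copy number n
(normal ploidy fixed at 2; no renormalization for overall tumor ploidy —
the lattice is diploid-anchored).

Pipeline stages and defaults:

1. **Normalization** — depths divided by per-sample totals;
   regions with normal depth < 10 masked.
2. **GC correction** — 40 equal-width GC bins; each raw ratio divided by
   its bin's median. This removes a multiplicative GC trend without
   assuming its shape.
3. **Smoothing** — centered moving average, window 5 regions, bounded
   within chromosomes.
4. **Peak detection** — Gaussian KDE of the smoothed ratios on a
   512-point grid over [0, 3] (Silverman bandwidth), Mexican-hat CWT at
   scales 2–32, keeping grid points that are local CWT maxima over ≥3
   scales; the global density mode is the fallback, so at least one peak
   is always returned.
5. **Gaussian mixture EM** — seeded at the wavelet peaks; sigma floored
   at 0.01; components below weight 0.02 pruned with restart;
   convergence at ΔLL < 1e-6 or 500 iterations. "Multi-component
   Gaussian model" is the reading adopted for peak approximation (a
   mixture over a ratio density), not complex-valued Gaussians.
6. **HMM segmentation** — states are the fitted peaks, emissions their
   Gaussians, stay probability 1−τ with τ = 1e-4, uniform switching;
   Viterbi per chromosome; same-state runs merge into segments.
7. **Allelic imbalance** — heterozygous SNPs (normal alt fraction in
   [0.35, 0.65], depth ≥ 20); per segment the mirrored BAF is the mean of
   max(f, 1−f) with ≥10 SNPs required. States: imbalanced above
   0.5 + 0.08, LOH above 0.70, cnLOH when LOH coincides with integer
   CN 2.
8. **Purity** — from LOH allelic imbalance (hemizygous-deletion
   inversion α = 2 − 1/m for deletion-range ratios, cnLOH inversion
   α = 2m − 1 near ratio 1), segment estimates combined by a
   SNP-count-weighted median; else from the somatic-VAF density mode
   (α = 2 × mode, ≥20 variants); else the constant 0.2. For purity
   estimation, imbalanced segments in the deletion ratio range are
   treated as hemizygous-deletion LOH even below the 0.70 annotation
   threshold — at purities under ~0.55 a hemizygous deletion cannot reach
   mirrored BAF 0.70, yet its imbalance is exactly the purity signal.
9. **Joint lattice fit** — the final α and integer CNs come from a scan
   over candidate purities (coarse 0.05 grid over [0.2, 1], then a fine
   0.01 grid around the best candidate; restricted to ±0.2 around the
   initial estimate when one exists). For each candidate, an HMM with
   states pinned to the lattice r(0..8) segments the track, and the score
   is the segment-size-weighted squared residual of segment means to
   their states plus an equally weighted allelic-imbalance term comparing
   each informative segment's mirrored BAF to the closest allelic
   configuration at its copy number. Ties break toward the initial
   estimate, then toward smaller α.

Two numerical choices in stage 9 matter. First, the score uses *segment
means*, not per-region residuals: per-region residuals always favor an
over-fine lattice (smaller α) because a denser state comb fits noise
better, while segment means average the noise away and expose the
quantization misfit of a wrong lattice. Second, the expected mirrored BAF
includes a finite-depth folded-normal correction: with binomial read
sampling at depth d, E[max(f̂, 1−f̂)] exceeds max(f, 1−f) — by ≈0.04 at
f = 0.5, d = 100 — and ignoring this biases the purity fit low through
the copy-neutral branch.

The lattice scan is what resolves copy-number states at low purity: at
α = 0.3 the single-copy ratio spacing (0.15) is comparable to the
smoothed per-region noise (sd ≈ 0.066 at depth 100), the ratio density is
effectively unimodal, and no density-based peak finder can separate the
states — only the HMM's spatial pooling can. The α/2 lattice aliasing
(every peak of a purity-α genome also lies on the α/2 lattice) is broken
by the allelic-imbalance term.

Copy-number frequencies across samples count integer CN > 2 as gain and
CN < 2 *or copy-neutral LOH* as loss, loss taking precedence, so each
sample contributes at most one category per bin.

Coordinates are 0-based half-open internally; variant tables are 1-based
on disk; SEG output stores log2 of the segment mean ratio.

## Somatic-variant filtering

Filters accumulate named flags, so the verdict is independent of
application order. Defaults: Fisher p < 0.01 with normal VAF ≤ 0.03
(germline bound); tumor depth ≥ 8; alt reads ≥ 3; strand bias when the
two-sided binomial p < 0.01 *and* the minor strand carries < 5% of alt
reads; homopolymer flag for indels adjacent to runs of ≥5 identical
bases. The purity adjustment is vaf/α capped at 1 — the allele frequency
rescaled to the tumor-cell compartment under a copy-number-neutral
assumption — with the ≥15% retention rule applied to the adjusted value;
the alternative cancer-cell-fraction scaling 2·vaf/α was considered and
not used because the retention threshold is stated for an allele
frequency. Consequence classes come from strand-aware codon translation
(standard table, via Biopython) for CDS SNVs, a ±2 bp splice window at
exon boundaries, and the mod-3 rule for CDS indels. RNA concordance
counts a DNA call as assessable at RNA depth > 10 and concordant with ≥1
alt-supporting RNA read. Hypermutators are flagged above 5× the cohort
median nonsynonymous count — a declared heuristic, since the original
identification was narrative (mismatch-repair inactivation).

## Methylation

Beta = M/(U + M + 100) exactly; the +100 offset bounds beta in [0, 1).
Probe filtering removes X/Y and SNP-associated probes, intersects probe
sets across platforms, drops probes missing in >20% of samples, and
orders output genomically. Variability ranking uses the n−1 sample SD
with lexicographic tie-breaks. Consensus k-means resamples 80% of
samples 100 times (k-means with 10 random starts, ≤1000 iterations,
Euclidean, samples as points in probe space); consensus(i,j) is the
co-clustering count over the co-sampling count; final labels cut the
average-linkage tree of 1 − consensus at k. Resampling parameters and
the label-assignment rule are this package's choices where the original
tooling left them implicit.

Promoter methylation averages probes within ±1500 bp of the TSS
(inclusive); a probe linked to several genes contributes to each.
Differential promoters: Welch *t*, BH over all tested genes, significant
at q < 0.01 and |Δβ| > 0.2 (the magnitude rule, with the sign retained in
the output, since hypo- and hypermethylated genes are both of interest).
Stratification thresholds are beta < 0.5 (hypo), [0.5, 0.7)
(intermediate), ≥ 0.7 (hyper). Distal selection restricts to probes
>1500 bp from every linked TSS, tests hypo vs hyper strata, and keeps
q < 1e−10 with Δβ < −0.25 — the q threshold reads a printed "1 × 10^10"
as 1e−10, since a q-value cannot exceed 1 and the criterion is described
as strict; it is configurable. Exported windows are [pos−500, pos+500)
clamped at the chromosome start.

## Expression and fusions

FPKM = counts × 1e9 / (exonic length × total mapped fragments) on the
longest isoform (ties by isoform id). The enrichment score is the
weighted KS running sum with weight exponent 1 on |score|; the null is
gene-set permutation (1000 random same-size sets), chosen over phenotype
permutation to keep the statistic well-defined at small sample counts;
NES divides ES by the mean |permuted ES| of the same sign and q is the
fraction of same-sign permuted NES at least as extreme. Because the
ranking metric was unspecified, genes are ranked by signal-to-noise
(mean difference over summed SDs, SDs floored at 0.2×|mean|), the
canonical default. Published NES/q values are therefore not exact
reproduction targets. Fusion rules: both flanks ≥12 bases per read,
qualifying reads > 4 (i.e. ≥5), and same-chromosome distance ≥ 100,000 bp
(inclusive); junction reads group into candidates within a 5 bp
breakpoint tolerance.

## Synthetic data

The generators emulate the statistical structure the stages assume, with
every dataset accompanied by machine-readable truth:

- **Exome** — normal depth negative-binomial around 100× with variance
  mean·(1 + 0.1) (mild extra-Poisson noise; at depth 100 with window-5
  smoothing this yields per-region ratio noise of sd ≈ 0.066, the regime
  the recovery tests target); tumor depth scaled by r(n); a shared
  multiplicative GC bias; per-region GC drawn i.i.d. (real capture GC is
  essentially independent of copy-number geography — tying GC to position
  would let entire CN blocks monopolize GC bins and corrupt the
  bin-median correction); het-SNP counts binomial from the
  two-population allele mixture. Default genome: 2000 regions over 4
  chromosomes, 72% copy-neutral, a hemizygous deletion (12%), a
  single-copy gain (10%), cnLOH (10%), and a two-copy gain (6%).
- **Somatic candidates** — clonal heterozygous variants at
  vaf = ccf·α/2, sequencing-error alt reads in the normal (rate 0.001),
  and three artifact classes (strand-concentrated, germline leak at VAF
  0.5, low depth).
- **Methylation** — cluster archetypes from a Beta(2,10)/Beta(10,2)
  mixture with truncated Gaussian noise; in the two-group scenario the
  planted differential promoters (and optionally distal probes) are
  hypermethylated in the reference group and shifted down by Δβ in
  group 0, so promoter-based stratification reproduces the group split;
  X/Y and SNP decoy probes included.
- **Junction reads** — true interchromosomal fusions with ≥12 bp flanks
  and ≥5 reads; decoys each fail exactly one rule.
- **Survival** — exponential event times, uniform censoring on
  (0, 60) months.

What the generators do **not** emulate: mappability and capture-
efficiency structure beyond GC, subclonal copy number, correlated
methylation of neighboring probes, batch effects, or sequence-context
error profiles. Passing the recovery tests therefore demonstrates the
correctness of the algorithms under their stated model, not performance
on real cohorts.

## Problem sizes

The recovery suites use the generators' default conditions: 2000 capture
regions at depth 100 across purities {0.3, 0.5, 0.7, 0.9} (20 seeds
each); 2000 genes with 40 planted differential promoters at the study's
18 vs 123 group split; 60 samples × 800 probes with six planted subtypes
for consensus clustering (the top-8000-SD selection scaled to top-400 of
800); 1000 planted somatics against 1000 artifacts; 2000-replicate null
calibrations for the log-rank and exclusivity tests. The exclusivity
calibration uses 200 samples per replicate: Fisher's exact test is
intrinsically conservative on small discrete tables (at 17 samples its
null rejection rate is ≈0.015), so calibration against the nominal level
is only meaningful where the table support is rich enough.

## Known limitations

- The diploid-anchored lattice cannot distinguish a genome-doubled tumor
  from its diploid counterpart; no ploidy renormalization is attempted.
- Purity below ~0.2 is not scanned for: single-copy ratio shifts (≤0.06)
  sit below the depth-100 noise floor, and the engine falls back to the
  default constant rather than over-fit; it always returns a valid
  estimate.
- The heuristic artifact filter set is configurable but not exhaustive;
  the original integrated genotyper's exact rule set is unpublished.
- Consensus clustering recomputes k-means per resample without warm
  starts; for the intended sample counts (tens to hundreds) this is
  fast, but it is not tuned for thousands of samples.
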