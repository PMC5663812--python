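"""Seeded generators for every input class, with known ground truth.

Each generator emulates the statistical structure the analysis stages
assume in real data — two-population (tumor/normal) read mixtures for
exome depth and allele counts, bimodal Infinium beta-values with planted
clusters and differential promoters, junction-read tables with designed
accept/reject fusions, and exponential survival with uniform censoring.
Ground truth sufficient to score every downstream stage is returned (and
written) alongside the data; the same seed and configuration reproduce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copynumber import HetSNP, RegionDepth
from .stats import SurvivalRecord
from .transcriptome import JunctionRead

__all__ = [
    "CNSegmentSpec",
    "default_cn_profile",
    "simulate_tumor_exome",
    "simulate_somatic_candidates",
    "simulate_beta_matrix",
    "simulate_junction_reads",
    "simulate_survival",
]


@dataclass(frozen=True)
class CNSegmentSpec:
    """True copy-number segment: region count, integer CN, allelic state.

    ``allelic_state`` is one of balanced / LOH / cnLOH; for LOH states the
    minor-allele copy count is 0.
    """

    n_regions: int
    cn: int
    allelic_state: str = "balanced"

    def __post_init__(self) -> None:
        if self.cn < 0 or self.n_regions <= 0:
            raise ValueError("invalid CN profile entry")
        if self.allelic_state == "cnLOH" and self.cn != 2:
            raise ValueError("cnLOH requires CN 2")


def default_cn_profile(n_regions: int = 2000) -> list[CNSegmentSpec]:
    """A diploid-dominant genome exercising CNs 1-4 plus cnLOH."""
    blocks = [
        (0.30, 2, "balanced"),
        (0.12, 1, "LOH"),
        (0.18, 2, "balanced"),
        (0.10, 3, "balanced"),
        (0.10, 2, "cnLOH"),
        (0.14, 2, "balanced"),
        (0.06, 4, "balanced"),
    ]
    out = []
    used = 0
    for frac, cn, state in blocks[:-1]:
        k = int(round(frac * n_regions))
        out.append(CNSegmentSpec(k, cn, state))
        used += k
    out.append(CNSegmentSpec(n_regions - used, blocks[-1][1], blocks[-1][2]))
    return out


def _minor_copies(spec: CNSegmentSpec) -> int:
    if spec.allelic_state in ("LOH", "cnLOH"):
        return 0
    return spec.cn // 2


def _nbinom_params(mean: float, overdispersion: float) -> tuple[float, float]:
    # var = mean * (1 + overdispersion): mild extra-Poisson noise
    r = mean / overdispersion
    p = r / (r + mean)
    return r, p


def simulate_tumor_exome(
    alpha: float,
    cn_profile: Optional[Sequence[CNSegmentSpec]] = None,
    n_regions: int = 2000,
    depth_mean: float = 100.0,
    overdispersion: float = 0.1,
    snps_per_region: float = 0.5,
    snp_depth_mean: float = 100.0,
    gc_bias_amplitude: float = 0.3,
    n_chromosomes: int = 4,
    seed: int = 17,
) -> tuple[list[RegionDepth], list[HetSNP], dict]:
    """Tumor/normal capture-region depths and het-SNP allele counts.

    Normal depth is negative-binomial around ``depth_mean`` modulated by
    a smooth GC bias curve; tumor depth is scaled by the two-population
    ratio (2(1-alpha) + n*alpha)/2 of each region's true CN under the
    same bias.  Het-SNP tumor alt counts are binomial with success
    probability from the allele mixture implied by CN and allelic state.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    profile = list(cn_profile) if cn_profile is not None else default_cn_profile(n_regions)
    n_regions = sum(s.n_regions for s in profile)
    rng = np.random.default_rng(seed)

    # region layout: contiguous 1 kb targets split evenly across chromosomes
    per_chrom = math.ceil(n_regions / n_chromosomes)
    chroms, starts = [], []
    for i in range(n_regions):
        chroms.append(f"chr{i // per_chrom + 1}")
        starts.append((i % per_chrom) * 2000)
    # per-region GC is essentially independent of genomic position, so every
    # GC stratum samples the genome-wide copy-number mixture
    gc = np.clip(rng.normal(0.45, 0.10, n_regions), 0.2, 0.8)
    gc_bias = 1.0 + gc_bias_amplitude * np.sin(2 * math.pi * (gc - 0.2) / 0.6)

    true_cn = np.concatenate([np.full(s.n_regions, s.cn) for s in profile])
    true_state = np.concatenate([np.full(s.n_regions, s.allelic_state, dtype=object) for s in profile])
    ratio_true = (2 * (1 - alpha) + true_cn * alpha) / 2.0

    r, p = _nbinom_params(depth_mean, overdispersion)
    depth_normal = rng.negative_binomial(r, p, n_regions) * gc_bias
    tum_mean = depth_mean * ratio_true
    depth_tumor = np.array(
        [rng.negative_binomial(*_nbinom_params(m, overdispersion)) for m in tum_mean]
    ) * gc_bias

    regions = [
        RegionDepth(
            chrom=chroms[i],
            start=starts[i],
            end=starts[i] + 1000,
            gc_fraction=float(gc[i]),
            depth_tumor=float(depth_tumor[i]),
            depth_normal=float(depth_normal[i]),
        )
        for i in range(n_regions)
    ]

    # heterozygous SNPs: Poisson-placed, binomial allele counts
    n_snps = rng.poisson(snps_per_region * n_regions)
    snp_region = np.sort(rng.integers(0, n_regions, n_snps))
    snps = []
    for ri in snp_region:
        spec_cn = int(true_cn[ri])
        minor = _minor_copies(
            CNSegmentSpec(1, spec_cn, str(true_state[ri])) if spec_cn > 0 else CNSegmentSpec(1, 0)
        ) if spec_cn > 0 else 0
        major = spec_cn - minor
        # the alt allele is randomly the major or the minor haplotype
        b_t = major if rng.random() < 0.5 else minor
        tot_alleles = 2 * (1 - alpha) + spec_cn * alpha
        f = ((1 - alpha) * 1 + alpha * b_t) / tot_alleles if tot_alleles > 0 else 0.5
        dt = max(int(rng.poisson(snp_depth_mean * ratio_true[ri])), 1)
        dn = max(int(rng.poisson(snp_depth_mean)), 1)
        alt_t = int(rng.binomial(dt, f))
        alt_n = int(rng.binomial(dn, 0.5))
        snps.append(
            HetSNP(
                chrom=chroms[ri],
                pos=starts[ri] + int(rng.integers(0, 1000)),
                ref_count_tumor=dt - alt_t,
                alt_count_tumor=alt_t,
                ref_count_normal=dn - alt_n,
                alt_count_normal=alt_n,
            )
        )

    # truth segment table in genomic coordinates
    truth_segments = []
    i = 0
    for s in profile:
        members = range(i, i + s.n_regions)
        # a profile block may straddle a chromosome boundary; split it
        block: list[int] = []
        for m in members:
            if block and chroms[m] != chroms[block[0]]:
                truth_segments.append(
                    dict(chrom=chroms[block[0]], start=starts[block[0]],
                         end=starts[block[-1]] + 1000, cn=s.cn, allelic_state=s.allelic_state)
                )
                block = []
            block.append(m)
        truth_segments.append(
            dict(chrom=chroms[block[0]], start=starts[block[0]],
                 end=starts[block[-1]] + 1000, cn=s.cn, allelic_state=s.allelic_state)
        )
        i += s.n_regions
    truth = {
        "alpha_true": alpha,
        "cn_per_region": true_cn.astype(int),
        "state_per_region": true_state,
        "segments": truth_segments,
    }
    return regions, snps, truth


def simulate_somatic_candidates(
    alpha: float,
    n_true: int = 200,
    n_artifacts: int = 60,
    depth_mean: float = 120.0,
    clonal_fraction: float = 1.0,
    error_rate: float = 0.001,
    seed: int = 17,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Somatic-candidate table with planted true variants and artifacts.

    True somatics are heterozygous in the tumor compartment: expected raw
    VAF = ccf * alpha / 2.  Artifact classes: strand_bias (all alt reads
    on one strand), germline_leak (normal VAF near 0.5), low_depth.
    Returns (candidates, truth) DataFrames sharing a ``variant_id``.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    bases = np.array(list("ACGT"))
    vid = 0

    def draw_alleles():
        ref, alt = rng.choice(4, size=2, replace=False)
        return bases[ref], bases[alt]

    for _ in range(n_true):
        vaf = clonal_fraction * alpha / 2.0
        dt = max(int(rng.poisson(depth_mean)), 8)
        dn = max(int(rng.poisson(depth_mean)), 8)
        alt_t = int(rng.binomial(dt, vaf))
        alt_n = int(rng.binomial(dn, error_rate))
        fwd = int(rng.binomial(alt_t, 0.5))
        ref, alt = draw_alleles()
        rows.append(dict(variant_id=vid, chrom="chr1", pos=vid * 1000, ref=ref, alt=alt,
                         tumor_ref=dt - alt_t, tumor_alt=alt_t, normal_ref=dn - alt_n,
                         normal_alt=alt_n, strand_fwd_alt=fwd, strand_rev_alt=alt_t - fwd))
        truth_rows.append(dict(variant_id=vid, is_artifact=False, artifact_class="",
                               clonal_fraction=clonal_fraction))
        vid += 1

    classes = ["strand_bias", "germline_leak", "low_depth"]
    for j in range(n_artifacts):
        cls = classes[j % len(classes)]
        dt = max(int(rng.poisson(depth_mean)), 8)
        dn = max(int(rng.poisson(depth_mean)), 8)
        if cls == "strand_bias":
            alt_t = max(int(rng.binomial(dt, 0.3)), 12)
            fwd, alt_n = alt_t, int(rng.binomial(dn, error_rate))
        elif cls == "germline_leak":
            alt_t = int(rng.binomial(dt, 0.5))
            alt_n = int(rng.binomial(dn, 0.5))
            fwd = int(rng.binomial(alt_t, 0.5))
        else:  # low_depth
            dt = int(rng.integers(2, 6))
            alt_t = max(int(rng.binomial(dt, 0.5)), 1)
            alt_n = 0
            fwd = int(rng.binomial(alt_t, 0.5))
        ref, alt = draw_alleles()
        rows.append(dict(variant_id=vid, chrom="chr1", pos=vid * 1000, ref=ref, alt=alt,
                         tumor_ref=dt - alt_t, tumor_alt=alt_t, normal_ref=dn - alt_n,
                         normal_alt=alt_n, strand_fwd_alt=fwd, strand_rev_alt=alt_t - fwd))
        truth_rows.append(dict(variant_id=vid, is_artifact=True, artifact_class=cls,
                               clonal_fraction=0.0))
        vid += 1
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_beta_matrix(
    n_clusters: int = 6,
    samples_per_cluster: int = 10,
    n_probes: int = 800,
    n_genes: int = 100,
    n_differential_genes: int = 0,
    delta_beta: float = 0.35,
    n_differential_distal: int = 0,
    distal_delta_beta: float = 0.40,
    noise_sd: float = 0.05,
    probes_per_gene: int = 3,
    n_xy_probes: int = 20,
    n_snp_probes: int = 10,
    group_split: Optional[tuple[int, int]] = None,
    seed: int = 17,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Beta matrix with planted clusters and differential promoters.

    Cluster archetypes draw each probe from a two-component Beta mixture
    (hypomethylated ~ Beta(2,10), hypermethylated ~ Beta(10,2)); samples
    add truncated Gaussian noise.  In the two-group scenario
    (``group_split``) the planted differential promoters — and, when
    ``n_differential_distal`` > 0, distal probes — are hypermethylated in
    the reference group 1 and hypomethylated by the stated shift in
    group 0.  Probes carry TSS-distance annotation (promoter and
    distal), plus X/Y and SNP-flagged decoys.

    Returns (beta DataFrame probes x samples, annotation DataFrame, truth).
    """
    rng = np.random.default_rng(seed)
    if group_split is not None:
        # two-group differential scenario: one shared archetype; only the
        # planted genes differ between the groups
        n_samples = sum(group_split)
        sample_groups = np.array([0] * group_split[0] + [1] * group_split[1])
        cluster_labels = sample_groups.copy()
        n_arch = 1
    else:
        n_samples = n_clusters * samples_per_cluster
        cluster_labels = np.repeat(np.arange(n_clusters), samples_per_cluster)
        sample_groups = cluster_labels
        n_arch = n_clusters

    # probe annotation: promoter probes for genes, distal probes, decoys
    n_promoter = n_genes * probes_per_gene
    n_distal = max(n_probes - n_promoter - n_xy_probes - n_snp_probes, 0)
    records = []
    pid = 0
    for g in range(n_genes):
        for k in range(probes_per_gene):
            records.append(dict(probe_id=f"cg{pid:07d}", chrom=f"chr{g % 5 + 1}",
                                pos=100000 * g + 500 * k, gene=f"GENE{g:04d}",
                                tss_distance=-700 + 700 * k, snp_associated=False))
            pid += 1
    for j in range(n_distal):
        records.append(dict(probe_id=f"cg{pid:07d}", chrom=f"chr{j % 5 + 1}",
                            pos=50_000_000 + 10_000 * j, gene="", tss_distance=5000 + 100 * j,
                            snp_associated=False))
        pid += 1
    for j in range(n_xy_probes):
        records.append(dict(probe_id=f"cg{pid:07d}", chrom="chrX" if j % 2 == 0 else "chrY",
                            pos=1000 * j, gene="", tss_distance=9999, snp_associated=False))
        pid += 1
    for j in range(n_snp_probes):
        records.append(dict(probe_id=f"cg{pid:07d}", chrom="chr1", pos=90_000_000 + 1000 * j,
                            gene="", tss_distance=9999, snp_associated=True))
        pid += 1
    annotation = pd.DataFrame(records)
    n_total = len(annotation)

    hypo = rng.beta(2, 10, size=(n_total, n_arch))
    hyper = rng.beta(10, 2, size=(n_total, n_arch))
    which = rng.random((n_total, n_arch)) < 0.5
    archetypes = np.where(which, hyper, hypo)

    arch_of_sample = sample_groups if n_arch > 1 else np.zeros(n_samples, dtype=int)
    beta = archetypes[:, arch_of_sample] + rng.normal(0, noise_sd, size=(n_total, n_samples))

    diff_genes: list[str] = []
    distal_planted: list[str] = []
    if n_differential_genes > 0:
        gene_ids = [f"GENE{g:04d}" for g in range(n_genes)]
        diff_genes = list(rng.choice(gene_ids, size=n_differential_genes, replace=False))
        promoter_idx = annotation.index[annotation["gene"].isin(diff_genes)].to_numpy()
        # group 1 (reference) hypermethylated at the planted promoters,
        # group 0 hypomethylated by delta_beta below it
        base = rng.uniform(0.70, 0.85, size=promoter_idx.size)
        g0, g1 = sample_groups == 0, sample_groups == 1
        beta[np.ix_(promoter_idx, np.where(g1)[0])] = (
            base[:, None] + rng.normal(0, noise_sd, (promoter_idx.size, int(g1.sum())))
        )
        beta[np.ix_(promoter_idx, np.where(g0)[0])] = (
            base[:, None] - delta_beta + rng.normal(0, noise_sd, (promoter_idx.size, int(g0.sum())))
        )
    if n_differential_distal > 0:
        is_distal = (annotation["gene"] == "") & (annotation["tss_distance"].abs() > 1500) \
            & ~annotation["chrom"].isin(["chrX", "chrY"]) & ~annotation["snp_associated"]
        distal_idx = rng.choice(annotation.index[is_distal].to_numpy(),
                                size=n_differential_distal, replace=False)
        base = rng.uniform(0.70, 0.85, size=distal_idx.size)
        g0, g1 = sample_groups == 0, sample_groups == 1
        beta[np.ix_(distal_idx, np.where(g1)[0])] = (
            base[:, None] + rng.normal(0, noise_sd, (distal_idx.size, int(g1.sum())))
        )
        beta[np.ix_(distal_idx, np.where(g0)[0])] = (
            base[:, None] - distal_delta_beta
            + rng.normal(0, noise_sd, (distal_idx.size, int(g0.sum())))
        )
        distal_planted = sorted(annotation.loc[distal_idx, "probe_id"])

    beta = np.clip(beta, 0.0, 1.0)
    samples = [f"S{j:03d}" for j in range(n_samples)]
    beta_df = pd.DataFrame(beta, index=annotation["probe_id"].to_numpy(), columns=samples)
    truth = {
        "cluster_labels": cluster_labels,
        "sample_groups": sample_groups,
        "differential_genes": sorted(diff_genes),
        "delta_beta": delta_beta,
        "differential_distal_probes": distal_planted,
    }
    return beta_df, annotation, truth


def simulate_junction_reads(
    n_true_fusions: int = 3,
    n_decoys: int = 20,
    true_read_count: int = 8,
    seed: int = 17,
) -> tuple[list[JunctionRead], pd.DataFrame]:
    """Junction reads for designed true fusions and failing decoys.

    True fusions are interchromosomal with >= ``true_read_count`` reads
    and flanks >= 12 bases.  Decoys fail exactly one rule each, cycling
    through: too few reads (<= 4), short flank (11 bases on one side),
    same-chromosome distance < 100 kb.
    """
    rng = np.random.default_rng(seed)
    reads: list[JunctionRead] = []
    truth_rows = []
    rid = 0

    def mk_reads(n, left, right, min_flank=12, short_side=None):
        nonlocal rid
        for _ in range(n):
            lf = int(rng.integers(min_flank, 40))
            rf = int(rng.integers(min_flank, 40))
            if short_side == "left":
                lf = 11
            elif short_side == "right":
                rf = 11
            reads.append(JunctionRead(read_id=f"r{rid:05d}", chrom_left=left[0], pos_left=left[1],
                                      strand_left="+", chrom_right=right[0], pos_right=right[1],
                                      strand_right="+", left_match_len=lf, right_match_len=rf))
            rid += 1

    for i in range(n_true_fusions):
        left = (f"chr{2 * i + 1}", 1_000_000 + i * 10_000)
        right = (f"chr{2 * i + 2}", 5_000_000 + i * 10_000)
        n = true_read_count + int(rng.integers(0, 4))
        mk_reads(n, left, right)
        truth_rows.append(dict(kind="true", chrom_left=left[0], pos_left=left[1],
                               chrom_right=right[0], pos_right=right[1], n_reads=n,
                               failing_rule=""))

    rules = ["few_reads", "short_flank", "read_through"]
    for j in range(n_decoys):
        rule = rules[j % len(rules)]
        if rule == "read_through":
            left = ("chr9", 10_000_000 + j * 300_000)
            right = ("chr9", left[1] + int(rng.integers(1_000, 99_000)))
        else:
            left = ("chr10", 1_000_000 + j * 200_000)
            right = ("chr11", 2_000_000 + j * 200_000)
        if rule == "few_reads":
            mk_reads(int(rng.integers(1, 5)), left, right)
        elif rule == "short_flank":
            mk_reads(6, left, right, short_side="left" if j % 2 else "right")
        else:
            mk_reads(6, left, right)
        truth_rows.append(dict(kind="decoy", chrom_left=left[0], pos_left=left[1],
                               chrom_right=right[0], pos_right=right[1], n_reads=0,
                               failing_rule=rule))
    return reads, pd.DataFrame(truth_rows)


def simulate_survival(
    hazard_ratio: float,
    n_per_group: tuple[int, int] = (30, 30),
    baseline_hazard: float = 0.05,
    censor_max: float = 60.0,
    seed: int = 17,
) -> tuple[list[SurvivalRecord], dict]:
    """Exponential event times per group with uniform censoring.

    Group "high" has hazard ``baseline_hazard * hazard_ratio``; censoring
    times are uniform on (0, censor_max) months.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for label, n, hz in [("low", n_per_group[0], baseline_hazard),
                         ("high", n_per_group[1], baseline_hazard * hazard_ratio)]:
        t_event = rng.exponential(1.0 / hz, n)
        t_cens = rng.uniform(0, censor_max, n)
        for te, tc in zip(t_event, t_cens):
            records.append(SurvivalRecord(time=float(min(te, tc)), event=bool(te <= tc), group=label))
    truth = {"hazard_low": baseline_hazard, "hazard_high": baseline_hazard * hazard_ratio}
    return records, truth
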