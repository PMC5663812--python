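"""Expression quantification, gene-set enrichment, and fusion filtering.

FPKM is computed per gene on the longest isoform (ties broken by
isoform id).  Gene-set enrichment uses the weighted Kolmogorov-Smirnov
running sum (weight exponent 1 on the ranking score) with a gene-set
permutation null for NES and FDR q.  Fusion candidates built from
junction reads survive only with more than four qualifying reads
(>= 12 matched bases on both sides of the breakpoint in each read) and,
for same-chromosome pairs, a breakpoint distance of at least 100,000 bp
to exclude read-through transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, wilcoxon_rank_sum

__all__ = [
    "GeneModel",
    "EnrichmentResult",
    "JunctionRead",
    "FusionCandidate",
    "select_longest_isoform",
    "fpkm",
    "rank_by_signal_to_noise",
    "gsea",
    "compare_gene_expression",
    "group_junction_reads",
    "fusion_filter",
    "correlate_promoter_expression",
]

MIN_FLANK_BP = 12
MIN_SPANNING_READS = 5  # "more than four reads"
MIN_INTRACHROM_DISTANCE = 100_000


@dataclass
class GeneModel:
    """Gene with one or more isoforms as exon-interval lists."""

    gene: str
    isoforms: dict[str, list[tuple[int, int]]]
    chrom: str = "chr1"
    strand: str = "+"
    selected_isoform: Optional[str] = None

    def exonic_length(self, isoform: str) -> int:
        return sum(e - s for s, e in self.isoforms[isoform])


def select_longest_isoform(models: Sequence[GeneModel]) -> list[GeneModel]:
    """Pick, per gene, the isoform with maximal summed exon length.

    Ties break lexicographically by isoform id.
    """
    out = []
    for m in models:
        if not m.isoforms:
            raise ValueError(f"gene {m.gene} has no isoforms")
        best = min(m.isoforms, key=lambda iso: (-m.exonic_length(iso), iso))
        out.append(GeneModel(gene=m.gene, isoforms=m.isoforms, chrom=m.chrom,
                             strand=m.strand, selected_isoform=best))
    return out


def fpkm(
    counts: pd.DataFrame, models: Sequence[GeneModel], total_mapped: pd.Series | dict
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    ``counts`` is gene x sample fragment counts; lengths come from each
    gene's selected (longest) isoform.
    """
    models = select_longest_isoform(models)
    lengths = {m.gene: m.exonic_length(m.selected_isoform) for m in models}
    totals = pd.Series(total_mapped)
    if (totals <= 0).any():
        raise ValueError("total mapped fragments must be positive")
    missing = [g for g in counts.index if g not in lengths]
    if missing:
        raise ValueError(f"no gene model for {missing[:3]}")
    length_vec = pd.Series({g: lengths[g] for g in counts.index})
    if (length_vec <= 0).any():
        raise ValueError("zero-length gene model")
    return counts.mul(1e9).div(length_vec, axis=0).div(totals, axis=1)


def rank_by_signal_to_noise(
    expression: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str],
    sd_floor_frac: float = 0.2,
) -> pd.Series:
    """Per-gene signal-to-noise ranking, descending.

    score = (mean_a - mean_b) / (sd_a + sd_b), each sd floored at
    ``sd_floor_frac`` of |mean| (and a small absolute floor), the
    convention of the canonical enrichment tool.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    xa = expression[list(group_a)].to_numpy(float)
    xb = expression[list(group_b)].to_numpy(float)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    sa = np.maximum(xa.std(axis=1, ddof=1), np.maximum(sd_floor_frac * np.abs(ma), 1e-8))
    sb = np.maximum(xb.std(axis=1, ddof=1), np.maximum(sd_floor_frac * np.abs(mb), 1e-8))
    score = (ma - mb) / (sa + sb)
    return pd.Series(score, index=expression.index).sort_values(ascending=False, kind="mergesort")


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    q_value: float
    leading_edge: list[str]
    running_sum: np.ndarray = field(repr=False, default=None)


def _running_sum(scores: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    weights = np.abs(scores) * in_set
    n_miss = (~in_set.astype(bool)).sum()
    hit_denom = weights.sum()
    if hit_denom == 0:  # all-zero scores inside the set: fall back to unweighted
        weights = in_set.astype(float)
        hit_denom = weights.sum()
    p_hit = np.cumsum(weights) / hit_denom
    p_miss = np.cumsum(~in_set.astype(bool)) / max(n_miss, 1)
    return p_hit - p_miss


def _es_from_running(run: np.ndarray) -> float:
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea(
    ranked_scores: pd.Series,
    gene_set: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 17,
) -> EnrichmentResult:
    """Weighted-KS enrichment of a gene set in a ranked gene list.

    ES is the signed extremum of the running sum; the null is gene-set
    permutation (random member sets of the same size).  NES divides ES
    by the mean |permuted ES| of the same sign; q is the fraction of
    same-sign permuted NES at least as extreme.
    """
    genes = np.asarray(ranked_scores.index)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in ranking")
    scores = ranked_scores.to_numpy(float)
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    in_set = np.isin(genes, list(members))
    run = _running_sum(scores, in_set)
    es = _es_from_running(run)

    rng = np.random.default_rng(seed)
    k = int(in_set.sum())
    perm_es = np.empty(n_permutations)
    for i in range(n_permutations):
        sel = np.zeros(genes.size, dtype=bool)
        sel[rng.choice(genes.size, size=k, replace=False)] = True
        perm_es[i] = _es_from_running(_running_sum(scores, sel))

    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    denom = np.abs(same_sign).mean() if same_sign.size else np.abs(perm_es).mean()
    nes = es / denom if denom > 0 else 0.0
    if same_sign.size:
        q = float((np.abs(same_sign / denom) >= abs(nes) - 1e-12).mean())
    else:
        q = 1.0 / (n_permutations + 1)
    q = min(max(q, 0.0), 1.0)

    peak = int(np.argmax(np.abs(run)))
    if es >= 0:
        leading = [g for g, m in zip(genes[: peak + 1], in_set[: peak + 1]) if m]
    else:
        leading = [g for g, m in zip(genes[peak:], in_set[peak:]) if m]
    return EnrichmentResult(es=es, nes=float(nes), q_value=q, leading_edge=leading,
                            running_sum=run)


def compare_gene_expression(
    expression: pd.DataFrame, gene: str, group_a: Sequence[str], group_b: Sequence[str]
) -> TestResult:
    """Wilcoxon rank-sum comparison of one gene's expression between groups."""
    if gene not in expression.index:
        raise KeyError(f"gene {gene} absent from the expression matrix")
    return wilcoxon_rank_sum(
        expression.loc[gene, list(group_a)].to_numpy(float),
        expression.loc[gene, list(group_b)].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# fusions


@dataclass(frozen=True)
class JunctionRead:
    read_id: str
    chrom_left: str
    pos_left: int
    strand_left: str
    chrom_right: str
    pos_right: int
    strand_right: str
    left_match_len: int
    right_match_len: int

    @property
    def qualifies(self) -> bool:
        return self.left_match_len >= MIN_FLANK_BP and self.right_match_len >= MIN_FLANK_BP


@dataclass
class FusionCandidate:
    chrom_left: str
    pos_left: int
    chrom_right: str
    pos_right: int
    reads: list[JunctionRead]

    @property
    def same_chromosome(self) -> bool:
        return self.chrom_left == self.chrom_right

    @property
    def distance(self) -> Optional[int]:
        return abs(self.pos_right - self.pos_left) if self.same_chromosome else None

    @property
    def n_qualifying(self) -> int:
        return sum(r.qualifies for r in self.reads)


def group_junction_reads(
    reads: Sequence[JunctionRead], breakpoint_tolerance: int = 5
) -> list[FusionCandidate]:
    """Cluster reads into candidates by breakpoint pair within tolerance."""
    candidates: list[FusionCandidate] = []
    for r in sorted(reads, key=lambda x: (x.chrom_left, x.pos_left, x.chrom_right, x.pos_right)):
        placed = False
        for c in candidates:
            if (
                c.chrom_left == r.chrom_left
                and c.chrom_right == r.chrom_right
                and abs(c.pos_left - r.pos_left) <= breakpoint_tolerance
                and abs(c.pos_right - r.pos_right) <= breakpoint_tolerance
            ):
                c.reads.append(r)
                placed = True
                break
        if not placed:
            candidates.append(FusionCandidate(r.chrom_left, r.pos_left, r.chrom_right,
                                              r.pos_right, [r]))
    return candidates


def fusion_filter(
    candidates: Sequence[FusionCandidate],
    min_flank: int = MIN_FLANK_BP,
    min_reads: int = MIN_SPANNING_READS,
    min_distance: int = MIN_INTRACHROM_DISTANCE,
) -> list[FusionCandidate]:
    """Apply the three fusion-calling rules.

    A read qualifies only when both flanks match at least ``min_flank``
    bases; a candidate survives with at least ``min_reads`` qualifying
    reads and, when both breakpoints share a chromosome, a distance of
    at least ``min_distance`` bp.
    """
    out = []
    for c in candidates:
        n_q = sum(
            r.left_match_len >= min_flank and r.right_match_len >= min_flank for r in c.reads
        )
        if n_q < min_reads:
            continue
        if c.same_chromosome and c.distance < min_distance:
            continue
        out.append(c)
    return out


def correlate_promoter_expression(
    promoter_betas: pd.Series, expression: pd.Series
) -> tuple[float, float]:
    """Pearson correlation (r, r^2) of paired promoter beta and expression."""
    joined = pd.concat([promoter_betas, expression], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired samples")
    x = joined.iloc[:, 0].to_numpy(float)
    y = joined.iloc[:, 1].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r
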