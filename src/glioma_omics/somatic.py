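"""Somatic-variant candidate filtering and cohort summaries.

A candidate passes when (i) the tumor-vs-normal Fisher exact test on
allele counts is significant and the normal alt fraction stays below a
germline bound, (ii) no heuristic artifact filter fires (depth, alt-read
support, strand bias, homopolymer-adjacent indels), and (iii) the
variant allele frequency, rescaled to the tumor-cell compartment by the
estimated purity (vaf / alpha, capped at 1), reaches 15%.  Consequence
classes come from strand-aware codon translation against a transcript
model.  Cohort-level utilities flag hypermutators and test mutual
exclusivity of gene pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .stats import TestResult, fisher_exact_2x2

__all__ = [
    "SomaticCandidate",
    "TranscriptModel",
    "RnaValidationResult",
    "FilterConfig",
    "somatic_fisher_filter",
    "heuristic_filters",
    "adjust_vaf",
    "apply_filters",
    "classify_consequence",
    "rna_validate",
    "flag_hypermutator",
    "mutual_exclusivity",
]

VAF_RETENTION_THRESHOLD = 0.15


@dataclass
class SomaticCandidate:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    tumor_ref: int
    tumor_alt: int
    normal_ref: int
    normal_alt: int
    strand_fwd_alt: int = 0
    strand_rev_alt: int = 0
    vaf_adjusted: Optional[float] = None
    consequence: Optional[str] = None
    filter_flags: set = field(default_factory=set)

    @property
    def vaf_raw(self) -> float:
        tot = self.tumor_ref + self.tumor_alt
        return self.tumor_alt / tot if tot else math.nan

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def passes(self) -> bool:
        return not self.filter_flags


@dataclass
class FilterConfig:
    fisher_p: float = 0.01
    max_normal_vaf: float = 0.03
    min_tumor_depth: int = 8
    min_alt_reads: int = 3
    strand_p: float = 0.01
    strand_minor_fraction: float = 0.05
    homopolymer_min_run: int = 5


def somatic_fisher_filter(
    cand: SomaticCandidate, threshold: float = 0.01, max_normal_vaf: float = 0.03
) -> set:
    """Fisher test of tumor vs normal allele counts plus a germline bound.

    Returns the flags raised (empty set = pass).
    """
    flags = set()
    t_tot = cand.tumor_ref + cand.tumor_alt
    n_tot = cand.normal_ref + cand.normal_alt
    if t_tot == 0 or n_tot == 0:
        return {"no_depth"}
    if cand.normal_alt / n_tot > max_normal_vaf:
        flags.add("germline_evidence")
    p = fisher_exact_2x2(cand.tumor_alt, cand.tumor_ref, cand.normal_alt, cand.normal_ref).p_value
    if p >= threshold:
        flags.add("fisher")
    return flags


def _binomial_two_sided_p(k: int, n: int) -> float:
    # symmetric binomial(n, 1/2): P(|K - n/2| >= |k - n/2|)
    if n == 0:
        return 1.0
    from scipy.special import gammaln

    logs = gammaln(n + 1) - gammaln(np.arange(n + 1) + 1) - gammaln(n - np.arange(n + 1) + 1)
    pmf = np.exp(logs - n * math.log(2))
    dev = abs(k - n / 2)
    return float(pmf[np.abs(np.arange(n + 1) - n / 2) >= dev - 1e-9].sum())


def heuristic_filters(
    cand: SomaticCandidate,
    config: FilterConfig | None = None,
    context: Optional[str] = None,
) -> set:
    """Artifact filters: depth, alt support, strand bias, homopolymer indel.

    ``context`` is the reference sequence immediately flanking the site
    (used only for the homopolymer rule on indels).
    """
    cfg = config or FilterConfig()
    flags = set()
    if cand.tumor_ref + cand.tumor_alt < cfg.min_tumor_depth:
        flags.add("low_depth")
    if cand.tumor_alt < cfg.min_alt_reads:
        flags.add("low_alt_support")
    n_alt = cand.strand_fwd_alt + cand.strand_rev_alt
    if n_alt > 0:
        minor = min(cand.strand_fwd_alt, cand.strand_rev_alt)
        p = _binomial_two_sided_p(cand.strand_fwd_alt, n_alt)
        if p < cfg.strand_p and minor / n_alt < cfg.strand_minor_fraction:
            flags.add("strand_bias")
    if cand.is_indel and context:
        run = 1
        best = 1
        for a, b in zip(context, context[1:]):
            run = run + 1 if a == b else 1
            best = max(best, run)
        if best >= cfg.homopolymer_min_run:
            flags.add("homopolymer_indel")
    return flags


def adjust_vaf(vaf_raw: float, alpha: float) -> tuple[float, bool]:
    """Purity-adjusted VAF and the >= 15% retention verdict.

    The raw allele frequency is rescaled to the tumor-cell compartment
    (vaf / alpha, capped at 1, copy-number-neutral assumption).
    """
    if alpha <= 0:
        raise ValueError("purity must be positive")
    adj = min(1.0, vaf_raw / alpha)
    return adj, adj >= VAF_RETENTION_THRESHOLD


def apply_filters(
    cand: SomaticCandidate,
    alpha: float,
    config: FilterConfig | None = None,
    context: Optional[str] = None,
) -> SomaticCandidate:
    """Accumulate all filter flags; order of application is immaterial."""
    cfg = config or FilterConfig()
    cand.filter_flags |= somatic_fisher_filter(cand, cfg.fisher_p, cfg.max_normal_vaf)
    cand.filter_flags |= heuristic_filters(cand, cfg, context)
    if not math.isnan(cand.vaf_raw):
        cand.vaf_adjusted, retained = adjust_vaf(cand.vaf_raw, alpha)
        if not retained:
            cand.filter_flags.add("low_adjusted_vaf")
    else:
        cand.filter_flags.add("no_depth")
    return cand


# ---------------------------------------------------------------------------
# consequence classification


@dataclass
class TranscriptModel:
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order
    cds: list[tuple[int, int]]  # subset of exonic space, genomic order

    def __post_init__(self) -> None:
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError("exons must be ordered and non-overlapping")


SPLICE_WINDOW = 2


def _cds_sequence_and_offset(
    model: TranscriptModel, genome: dict[str, str], pos: int
) -> tuple[str, Optional[int]]:
    """Concatenated CDS (genomic strand) and the CDS offset of ``pos``."""
    seq_parts = []
    offset = None
    consumed = 0
    for s, e in model.cds:
        seq_parts.append(genome[model.chrom][s:e])
        if s <= pos < e:
            offset = consumed + (pos - s)
        consumed += e - s
    return "".join(seq_parts), offset


def classify_consequence(
    cand: SomaticCandidate, model: TranscriptModel, genome: dict[str, str]
) -> str:
    """Consequence class of a variant against one transcript model.

    SNVs inside the CDS are translated before and after substitution
    (strand-aware); SNVs within 2 bp of an exon-intron boundary are
    splice_site; CDS indels are frameshift unless the length change is a
    multiple of 3; everything else is noncoding.
    """
    if cand.chrom != model.chrom:
        raise ValueError("variant and transcript on different chromosomes")
    pos = cand.pos

    in_exon = any(s <= pos < e for s, e in model.exons)
    if not in_exon:
        near_boundary = any(
            0 < s - pos <= SPLICE_WINDOW or 0 < pos - (e - 1) <= SPLICE_WINDOW
            for s, e in model.exons
        )
        if near_boundary:
            return "splice_site"
        return "noncoding"

    in_cds = any(s <= pos < e for s, e in model.cds)
    if not in_cds:
        return "noncoding"

    if cand.is_indel:
        delta = abs(len(cand.alt) - len(cand.ref))
        return "frameshift" if delta % 3 else "inframe_indel"

    cds_seq, offset = _cds_sequence_and_offset(model, genome, pos)
    assert offset is not None
    ref_base = genome[cand.chrom][pos]
    if ref_base.upper() != cand.ref.upper():
        raise ValueError(f"reference mismatch at {cand.chrom}:{pos}")
    alt_seq = cds_seq[:offset] + cand.alt + cds_seq[offset + 1 :]
    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        alt_seq = str(Seq(alt_seq).reverse_complement())
        offset = len(cds_seq) - 1 - offset
    codon_i = offset // 3
    ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_codon = alt_seq[3 * codon_i : 3 * codon_i + 3]
    if len(ref_codon) < 3:
        return "noncoding"
    table = standard_dna_table
    ref_aa = "*" if ref_codon.upper() in table.stop_codons else table.forward_table.get(ref_codon.upper())
    alt_aa = "*" if alt_codon.upper() in table.stop_codons else table.forward_table.get(alt_codon.upper())
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    return "synonymous" if ref_aa == alt_aa else "missense"


# ---------------------------------------------------------------------------
# validation and cohort summaries


@dataclass(frozen=True)
class RnaValidationResult:
    n_assessable: int
    n_concordant: int

    @property
    def concordance_fraction(self) -> Optional[float]:
        return self.n_concordant / self.n_assessable if self.n_assessable else None


def rna_validate(
    candidates: Sequence[SomaticCandidate],
    rna_counts: dict[tuple[str, int], tuple[int, int]],
    depth_threshold: int = 10,
    min_support: int = 1,
) -> RnaValidationResult:
    """Concordance of DNA calls with RNA allele counts.

    ``rna_counts`` maps (chrom, pos) -> (rna_depth, rna_alt_reads).  A
    position is assessable when RNA depth exceeds ``depth_threshold``;
    it is concordant when at least ``min_support`` RNA reads carry the
    alternate allele.
    """
    assessable = concordant = 0
    for c in candidates:
        depth, alt = rna_counts.get((c.chrom, c.pos), (0, 0))
        if depth > depth_threshold:
            assessable += 1
            if alt >= min_support:
                concordant += 1
    return RnaValidationResult(assessable, concordant)


def flag_hypermutator(counts: Sequence[int], factor: float = 5.0) -> np.ndarray:
    """Flag samples whose nonsynonymous burden exceeds factor x cohort median."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 samples")
    return counts > factor * np.median(counts)


def mutual_exclusivity(
    status_a: Sequence[bool], status_b: Sequence[bool]
) -> tuple[int, TestResult]:
    """Co-occurrence count and Fisher exact p for two gene mutation vectors."""
    a = np.asarray(status_a, dtype=bool)
    b = np.asarray(status_b, dtype=bool)
    if a.size != b.size or a.size == 0:
        raise ValueError("status vectors must be non-empty and aligned")
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    return both, fisher_exact_2x2(both, a_only, b_only, neither)
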