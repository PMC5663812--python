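"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are plain TSV/CSV with header rows.  Genomic
coordinates are 0-based half-open internally; variant tables carry
1-based positions on disk (converted on read/write), and BED/SEG follow
their usual conventions.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .copynumber import CNSegment, HetSNP, PurityEstimate, RegionDepth
from .somatic import SomaticCandidate
from .stats import SurvivalRecord

__all__ = [
    "read_region_table",
    "write_region_table",
    "read_snp_table",
    "write_snp_table",
    "read_variant_table",
    "write_variant_table",
    "read_beta_csv",
    "write_beta_csv",
    "read_group_file",
    "read_survival_table",
    "write_survival_table",
    "write_seg",
    "write_segments_tsv",
    "write_bed",
    "write_purity_report",
    "read_purity_report",
]

REGION_COLUMNS = ["chrom", "start", "end", "gc", "depth_tumor", "depth_normal"]
SNP_COLUMNS = ["chrom", "pos", "ref_count_tumor", "alt_count_tumor",
               "ref_count_normal", "alt_count_normal"]
VARIANT_COLUMNS = ["CHROM", "POS", "REF", "ALT", "tumor_ref", "tumor_alt",
                   "normal_ref", "normal_alt", "strand_fwd_alt", "strand_rev_alt"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_region_table(path) -> list[RegionDepth]:
    """Region depth TSV: chrom, start, end (BED-like), gc, depths."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, REGION_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        if row["start"] >= row["end"]:
            raise ValueError(f"{path}: line {i + 2}: start >= end")
        out.append(RegionDepth(str(row["chrom"]), int(row["start"]), int(row["end"]),
                               float(row["gc"]), float(row["depth_tumor"]),
                               float(row["depth_normal"])))
    return out


def write_region_table(regions: Sequence[RegionDepth], path) -> None:
    pd.DataFrame(
        [(r.chrom, r.start, r.end, r.gc_fraction, r.depth_tumor, r.depth_normal) for r in regions],
        columns=REGION_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_snp_table(path) -> list[HetSNP]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SNP_COLUMNS, path)
    return [
        HetSNP(str(r["chrom"]), int(r["pos"]), int(r["ref_count_tumor"]),
               int(r["alt_count_tumor"]), int(r["ref_count_normal"]),
               int(r["alt_count_normal"]))
        for _, r in df.iterrows()
    ]


def write_snp_table(snps: Sequence[HetSNP], path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.ref_count_tumor, s.alt_count_tumor,
          s.ref_count_normal, s.alt_count_normal) for s in snps],
        columns=SNP_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> list[SomaticCandidate]:
    """Variant TSV with 1-based POS on disk, converted to 0-based."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, VARIANT_COLUMNS, path)
    return [
        SomaticCandidate(chrom=str(r["CHROM"]), pos=int(r["POS"]) - 1, ref=str(r["REF"]),
                         alt=str(r["ALT"]), tumor_ref=int(r["tumor_ref"]),
                         tumor_alt=int(r["tumor_alt"]), normal_ref=int(r["normal_ref"]),
                         normal_alt=int(r["normal_alt"]),
                         strand_fwd_alt=int(r["strand_fwd_alt"]),
                         strand_rev_alt=int(r["strand_rev_alt"]))
        for _, r in df.iterrows()
    ]


def write_variant_table(cands: Sequence[SomaticCandidate], path) -> None:
    rows = []
    for c in cands:
        rows.append((c.chrom, c.pos + 1, c.ref, c.alt, c.tumor_ref, c.tumor_alt,
                     c.normal_ref, c.normal_alt, c.strand_fwd_alt, c.strand_rev_alt))
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_beta_csv(path) -> pd.DataFrame:
    """Probes x samples beta matrix (probe ids in the first column)."""
    return pd.read_csv(path, index_col=0)


def write_beta_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


def read_group_file(path) -> pd.Series:
    """TSV of (sample, group)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "group"], path)
    return df.set_index("sample")["group"]


def read_survival_table(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["time", "event", "group"], path)
    return [SurvivalRecord(float(r["time"]), bool(int(r["event"])), str(r["group"]))
            for _, r in df.iterrows()]


def write_survival_table(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame([(r.time, int(r.event), r.group) for r in records],
                 columns=["time", "event", "group"]).to_csv(path, sep="\t", index=False)


def write_seg(segments: Sequence[CNSegment], sample: str, path) -> None:
    """SEG format: sample, chrom, start, end, num_mark, seg_mean (log2 ratio)."""
    rows = [
        (sample, s.chrom, s.start, s.end, s.n_regions,
         math.log2(s.mean_ratio) if s.mean_ratio > 0 else float("nan"))
        for s in segments
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "num_mark", "seg_mean"]) \
        .to_csv(path, sep="\t", index=False)


def write_segments_tsv(segments: Sequence[CNSegment], path) -> None:
    """Extended segment table with integer CN, allelic state, mirrored BAF."""
    rows = [
        (s.chrom, s.start, s.end, s.n_regions, s.mean_ratio,
         s.integer_cn if s.integer_cn is not None else "",
         s.allelic_state,
         s.mirrored_baf if s.mirrored_baf is not None else "",
         s.n_het_snps)
        for s in segments
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "n_regions", "mean_ratio",
                                "integer_cn", "allelic_state", "mirrored_baf",
                                "n_het_snps"]).to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED (0-based half-open): chrom, start, end [, name]."""
    cols = [c for c in ["chrom", "start", "end", "name"] if c in intervals.columns]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def write_purity_report(purity: PurityEstimate, path) -> None:
    Path(path).write_text(
        f"alpha\t{purity.alpha:.4f}\nmethod\t{purity.method}\nsupport\t{purity.support}\n"
    )


def read_purity_report(path) -> PurityEstimate:
    kv = dict(line.split("\t") for line in Path(path).read_text().splitlines() if line)
    return PurityEstimate(alpha=float(kv["alpha"]), method=kv["method"],
                          support=int(kv.get("support", 0)))
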