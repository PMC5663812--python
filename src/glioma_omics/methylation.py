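"""Infinium-style methylation processing.

Beta-values are M/(U+M+100).  Probe filtering removes X/Y and
SNP-associated probes and intersects platforms; the top-k most variable
probes (sample SD) feed consensus k-means clustering (resampled k-means,
co-clustering frequency matrix, average-linkage cut).  Promoter
methylation is the mean beta over probes within 1500 bp of a gene's TSS;
differential promoters use Welch's t with Benjamini-Hochberg q-values
and are called significant at q < 0.01 with |difference| > 0.2.  Samples
can be stratified by an anchor gene's promoter beta (hypo < 0.5 <=
intermediate < 0.7 <= hyper), and distal (>1500 bp from any TSS)
hypomethylated probes are selected for motif-discovery export.
"""

from __future__ import annotations

import math

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .stats import bh_adjust, welch_t_matrix

__all__ = [
    "beta_from_intensities",
    "filter_probes",
    "select_top_variable",
    "consensus_kmeans",
    "promoter_beta",
    "differential_promoters",
    "stratify_by_promoter",
    "select_distal_hypo_probes",
]

TSS_PROMOTER_WINDOW = 1500
SIGNIFICANT_Q = 0.01
SIGNIFICANT_DIFF = 0.2
STRATUM_HYPO_MAX = 0.5
STRATUM_HYPER_MIN = 0.7


def beta_from_intensities(methylated: float, unmethylated: float) -> float:
    """Infinium beta-value M / (U + M + 100); bounded in [0, 1)."""
    if methylated < 0 or unmethylated < 0:
        raise ValueError("intensities must be non-negative")
    return methylated / (unmethylated + methylated + 100.0)


def filter_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    reference_platform_sets: Sequence[set] = (),
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Drop X/Y probes, SNP-associated probes, and non-shared probes.

    ``annotation`` needs columns probe_id, chrom, pos, snp_associated.
    After filtering, probes are returned in deterministic genomic order.
    Probes missing in more than ``max_missing_fraction`` of samples are
    also removed.
    """
    ann = annotation.set_index("probe_id").loc[matrix.index]
    keep = ~ann["chrom"].isin(["chrX", "chrY", "X", "Y"]) & ~ann["snp_associated"].astype(bool)
    ids = set(matrix.index[keep])
    for platform in reference_platform_sets:
        ids &= set(platform)
    if not ids:
        raise ValueError("no probes survive the platform intersection")
    kept = ann.loc[sorted(ids)].sort_values(["chrom", "pos"])
    out = matrix.loc[kept.index]
    missing = out.isna().mean(axis=1)
    return out.loc[missing <= max_missing_fraction]


def select_top_variable(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k probes by across-sample standard deviation (ddof=1).

    Ties break by probe_id lexicographic order; sample permutation does
    not change the selected set.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(matrix):
        raise ValueError("k exceeds the probe count")
    sd = matrix.std(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda pid: (-sd[pid], pid))
    return matrix.loc[order[:k]]


def consensus_kmeans(
    matrix: pd.DataFrame,
    k: int = 6,
    n_start: int = 10,
    max_iter: int = 1000,
    resample_reps: int = 100,
    resample_frac: float = 0.8,
    seed: int = 17,
) -> tuple[pd.DataFrame, pd.Series]:
    """Consensus clustering of samples by resampled k-means.

    Each repetition subsamples ``resample_frac`` of the samples and runs
    k-means (samples as points in probe space, ``n_start`` restarts,
    ``max_iter`` iterations).  consensus(i, j) = co-clustering count /
    co-sampling count.  Final labels cut the average-linkage tree of
    1 - consensus at k clusters.
    """
    samples = list(matrix.columns)
    n = len(samples)
    if k > n:
        raise ValueError("k exceeds the sample count")
    x = matrix.to_numpy(float).T  # samples x probes
    if k == 1:
        consensus = pd.DataFrame(np.ones((n, n)), index=samples, columns=samples)
        return consensus, pd.Series(np.zeros(n, dtype=int), index=samples)

    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    m = max(int(round(resample_frac * n)), k)
    for _ in range(resample_reps):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=k, n_init=n_start, max_iter=max_iter,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        labels = km.fit_predict(x[idx])
        sampled[np.ix_(idx, idx)] += 1
        for c in range(k):
            members = idx[labels == c]
            together[np.ix_(members, members)] += 1
    with np.errstate(invalid="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    consensus = (consensus + consensus.T) / 2
    np.fill_diagonal(consensus, 1.0)
    consensus = np.clip(consensus, 0.0, 1.0)

    dist = squareform(1.0 - consensus, checks=False)
    tree = average(dist)
    labels = fcluster(tree, t=k, criterion="maxclust") - 1
    return (
        pd.DataFrame(consensus, index=samples, columns=samples),
        pd.Series(labels, index=samples),
    )


def promoter_beta(
    matrix: pd.DataFrame, annotation: pd.DataFrame, window: int = TSS_PROMOTER_WINDOW
) -> pd.DataFrame:
    """Gene x sample mean beta over probes within ``window`` bp of the TSS.

    A probe linked to several genes contributes to each; genes with no
    promoter probe are omitted.  Missing betas are dropped pairwise.
    """
    ann = annotation[annotation["gene"].astype(str) != ""]
    ann = ann[ann["tss_distance"].abs() <= window]
    ann = ann[ann["probe_id"].isin(matrix.index)]
    if ann.empty:
        raise ValueError("no promoter probes within the window")
    rows = []
    for gene, grp in ann.groupby("gene", sort=True):
        rows.append(matrix.loc[grp["probe_id"]].mean(axis=0).rename(gene))
    return pd.DataFrame(rows)


def differential_promoters(
    promoter_betas: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    q_threshold: float = SIGNIFICANT_Q,
    diff_threshold: float = SIGNIFICANT_DIFF,
) -> pd.DataFrame:
    """Per-gene Welch t with BH correction; difference = mean1 - mean2.

    Significant when q < ``q_threshold`` and |difference| >
    ``diff_threshold``.  Sorted by q, then |difference| descending.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >= 2 samples")
    g1 = promoter_betas[list(group1)].to_numpy(float)
    g2 = promoter_betas[list(group2)].to_numpy(float)
    t, p = welch_t_matrix(g1, g2)
    q = bh_adjust(p)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    out = pd.DataFrame(
        {
            "gene": promoter_betas.index,
            "mean_beta_group1": m1,
            "mean_beta_group2": m2,
            "difference": m1 - m2,
            "t": t,
            "p_value": p,
            "q_value": q,
        }
    )
    out["significant"] = (out["q_value"] < q_threshold) & (out["difference"].abs() > diff_threshold)
    return out.sort_values(["q_value", "difference"],
                           key=lambda s: s.abs() if s.name == "difference" else s,
                           ascending=[True, False]).reset_index(drop=True)


def stratify_by_promoter(promoter_betas: pd.DataFrame, anchor_gene: str) -> pd.Series:
    """Assign hypo / intermediate / hyper by the anchor promoter beta.

    hypo: beta < 0.5; intermediate: 0.5 <= beta < 0.7; hyper: beta >= 0.7.
    """
    if anchor_gene not in promoter_betas.index:
        raise KeyError(f"anchor gene {anchor_gene} has no promoter value")
    beta = promoter_betas.loc[anchor_gene]
    strata = pd.Series("intermediate", index=beta.index, dtype=object)
    strata[beta < STRATUM_HYPO_MAX] = "hypo"
    strata[beta >= STRATUM_HYPER_MIN] = "hyper"
    return strata


def select_distal_hypo_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    hypo_samples: Sequence[str],
    hyper_samples: Sequence[str],
    q_max: float = 1e-10,
    diff_max: float = -0.25,
    tss_window: int = TSS_PROMOTER_WINDOW,
    window_bp: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distal probes hypomethylated in the hypo stratum, plus BED windows.

    Restricts to probes with min |TSS distance| > ``tss_window``; per
    probe Welch t (hypo vs hyper) with BH q; keeps q < q_max and
    (mean_hypo - mean_hyper) < diff_max.  Returns the selected probe
    table and a BED frame of [pos - window/2, pos + window/2) intervals
    clamped at the chromosome start.
    """
    if len(hypo_samples) < 2 or len(hyper_samples) < 2:
        raise ValueError("each stratum needs >= 2 samples")
    min_dist = annotation.groupby("probe_id")["tss_distance"].agg(lambda s: s.abs().min())
    distal_ids = [pid for pid in matrix.index if min_dist.get(pid, np.inf) > tss_window]
    sub = matrix.loc[distal_ids]
    if sub.empty:
        return sub.iloc[:0], pd.DataFrame(columns=["chrom", "start", "end", "name"])
    g_hypo = sub[list(hypo_samples)].to_numpy(float)
    g_hyper = sub[list(hyper_samples)].to_numpy(float)
    _, p = welch_t_matrix(g_hypo, g_hyper)
    q = bh_adjust(p)
    diff = g_hypo.mean(axis=1) - g_hyper.mean(axis=1)
    keep = (q < q_max) & (diff < diff_max)
    selected = pd.DataFrame(
        {"probe_id": sub.index[keep], "difference": diff[keep], "q_value": q[keep]}
    )
    ann = annotation.drop_duplicates("probe_id").set_index("probe_id")
    half = window_bp // 2
    bed = pd.DataFrame(
        {
            "chrom": ann.loc[selected["probe_id"], "chrom"].to_numpy(),
            "start": np.maximum(ann.loc[selected["probe_id"], "pos"].to_numpy() - half, 0),
            "end": ann.loc[selected["probe_id"], "pos"].to_numpy() + half,
            "name": selected["probe_id"].to_numpy(),
        }
    )
    return selected, bed
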