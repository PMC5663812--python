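"""Exome depth-ratio copy-number engine with tumor-purity estimation.

The pipeline mirrors an integrated tumor/normal genotyper: per-capture-
region read depths are library-size normalized and GC-corrected, the
tumor/normal ratio is smoothed with a moving average, copy-number peaks
are located by a Mexican-hat continuous wavelet transform of the ratio
density and refined by 1-D Gaussian-mixture EM, a hidden Markov model
with those Gaussian emissions assigns each region to a peak (Viterbi),
heterozygous-SNP allelic imbalance classifies segments (balanced /
imbalanced / LOH / copy-neutral LOH), and a joint lattice fit of peak
positions against the two-population mixture model

    r(n) = (2 (1 - alpha) + n alpha) / 2

yields integer copy numbers and the tumor purity alpha.  When no LOH
segment is informative, purity falls back to the somatic-VAF
distribution, and finally to the constant 0.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pywt

__all__ = [
    "RegionDepth",
    "DepthRatioTrack",
    "CNPeak",
    "CNSegment",
    "HetSNP",
    "PurityEstimate",
    "CNConfig",
    "compute_depth_ratio",
    "detect_peaks_wavelet",
    "fit_gaussian_peaks",
    "segment_hmm",
    "allelic_imbalance",
    "estimate_purity_from_loh",
    "estimate_purity_from_vaf",
    "purity_fallback_chain",
    "fit_integer_cn",
    "cna_frequency",
    "run_cn_pipeline",
]

DEFAULT_PURITY = 0.2


@dataclass(frozen=True)
class RegionDepth:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    depth_tumor: float
    depth_normal: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction out of [0,1]")


@dataclass
class DepthRatioTrack:
    regions: list[RegionDepth]
    raw_ratio: np.ndarray
    gc_corrected_ratio: np.ndarray
    smoothed_ratio: np.ndarray
    mask: np.ndarray  # True where the region is usable
    library_size_tumor: float
    library_size_normal: float

    @property
    def usable_ratios(self) -> np.ndarray:
        return self.smoothed_ratio[self.mask]


@dataclass
class CNPeak:
    mean_ratio: float
    sigma: float
    weight: float
    assigned_cn: Optional[int] = None


@dataclass
class CNSegment:
    chrom: str
    start: int
    end: int
    peak_id: int
    mean_ratio: float
    n_regions: int
    integer_cn: Optional[int] = None
    allelic_state: str = "balanced"
    mirrored_baf: Optional[float] = None
    n_het_snps: int = 0
    mean_snp_depth: float = 0.0


@dataclass(frozen=True)
class HetSNP:
    chrom: str
    pos: int
    ref_count_tumor: int
    alt_count_tumor: int
    ref_count_normal: int
    alt_count_normal: int

    @property
    def tumor_alt_fraction(self) -> float:
        tot = self.ref_count_tumor + self.alt_count_tumor
        return self.alt_count_tumor / tot if tot else math.nan


@dataclass(frozen=True)
class PurityEstimate:
    alpha: float
    method: str  # loh_allelic_imbalance | vaf_distribution | default_constant
    support: int = 0


@dataclass
class CNConfig:
    """Tunables of the copy-number engine; defaults are the study settings."""

    min_normal_depth: float = 10.0
    n_gc_bins: int = 40
    smoothing_window: int = 5
    density_grid_size: int = 512
    density_range: tuple[float, float] = (0.0, 3.0)
    wavelet_scales: tuple[int, int] = (2, 32)
    min_ridge_scales: int = 3
    em_max_iter: int = 500
    em_tol: float = 1e-6
    em_min_weight: float = 0.02
    sigma_floor: float = 0.01
    hmm_tau: float = 1e-4
    het_band: tuple[float, float] = (0.35, 0.65)
    het_min_depth: int = 20
    min_snps_per_segment: int = 10
    imbalance_margin: float = 0.08
    loh_mirrored_baf: float = 0.70
    min_vaf_variants: int = 20
    max_cn: int = 8
    seed: int = 17


# ---------------------------------------------------------------------------
# depth ratio


def compute_depth_ratio(regions: Sequence[RegionDepth], config: CNConfig | None = None) -> DepthRatioTrack:
    """Normalized, GC-corrected, moving-average-smoothed tumor/normal ratio.

    Library-size normalization divides each depth by the sample's total;
    GC correction divides each raw ratio by the median raw ratio of its
    GC bin; smoothing is a centered moving average bounded within each
    chromosome.  Regions with normal depth below ``min_normal_depth``
    are masked out of all downstream steps.
    """
    cfg = config or CNConfig()
    regions = list(regions)
    if not regions:
        raise ValueError("no regions")
    lib_t = float(sum(r.depth_tumor for r in regions))
    lib_n = float(sum(r.depth_normal for r in regions))
    depth_t = np.array([r.depth_tumor for r in regions])
    depth_n = np.array([r.depth_normal for r in regions])
    gc = np.array([r.gc_fraction for r in regions])
    mask = depth_n >= cfg.min_normal_depth
    if not mask.any():
        raise ValueError("all regions fall below the minimum normal depth")

    raw = np.full(len(regions), np.nan)
    raw[mask] = (depth_t[mask] / lib_t) / (depth_n[mask] / lib_n)

    corrected = raw.copy()
    bins = np.clip((gc * cfg.n_gc_bins).astype(int), 0, cfg.n_gc_bins - 1)
    for b in range(cfg.n_gc_bins):
        sel = mask & (bins == b)
        if sel.sum() == 0:
            continue
        med = np.median(raw[sel])
        if med > 0:
            corrected[sel] = raw[sel] / med

    smoothed = corrected.copy()
    chroms = np.array([r.chrom for r in regions])
    half = cfg.smoothing_window // 2
    for chrom in dict.fromkeys(chroms):  # preserves order
        idx = np.where(chroms == chrom)[0]
        vals = corrected[idx]
        ok = mask[idx]
        out = vals.copy()
        for j in range(len(idx)):
            lo, hi = max(0, j - half), min(len(idx), j + half + 1)
            window = vals[lo:hi][ok[lo:hi]]
            if window.size:
                out[j] = window.mean()
        smoothed[idx] = out

    return DepthRatioTrack(
        regions=regions,
        raw_ratio=raw,
        gc_corrected_ratio=corrected,
        smoothed_ratio=smoothed,
        mask=mask,
        library_size_tumor=lib_t,
        library_size_normal=lib_n,
    )


# ---------------------------------------------------------------------------
# peak detection


def _ratio_density(ratios: np.ndarray, cfg: CNConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.density_range
    grid = np.linspace(lo, hi, cfg.density_grid_size)
    # Silverman bandwidth on the clipped ratios
    x = np.clip(ratios, lo, hi)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    bw = max(0.9 * scale * x.size ** (-0.2), 1e-3)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2).sum(axis=1)
    dens /= x.size * bw * math.sqrt(2 * math.pi)
    return grid, dens


def detect_peaks_wavelet(track_or_ratios, config: CNConfig | None = None) -> np.ndarray:
    """Candidate copy-number peak locations from a CWT of the ratio density.

    A Mexican-hat continuous wavelet transform is applied to a kernel-
    density estimate of the smoothed ratios on a fixed grid; grid points
    that are local maxima of the CWT coefficients over at least
    ``min_ridge_scales`` consecutive scales are reported (ascending).
    The global density mode is returned as a fallback so at least one
    peak always comes back.
    """
    cfg = config or CNConfig()
    if isinstance(track_or_ratios, DepthRatioTrack):
        ratios = track_or_ratios.usable_ratios
    else:
        ratios = np.asarray(track_or_ratios, dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < 50:
        raise ValueError("need at least 50 usable ratios for peak detection")

    grid, dens = _ratio_density(ratios, cfg)
    scales = np.arange(cfg.wavelet_scales[0], cfg.wavelet_scales[1] + 1)
    coeffs, _ = pywt.cwt(dens, scales, "mexh")

    # count, per grid point, over how many scales it is a local CWT maximum
    persistence = np.zeros(grid.size, dtype=int)
    for row in coeffs:
        is_max = np.zeros(grid.size, dtype=bool)
        interior = (row[1:-1] >= row[:-2]) & (row[1:-1] >= row[2:]) & (row[1:-1] > 0)
        is_max[1:-1] = interior
        persistence += is_max

    candidate = np.where(persistence >= cfg.min_ridge_scales)[0]
    peaks: list[float] = []
    if candidate.size:
        # merge runs of adjacent grid indices, keep the densest point of each
        splits = np.where(np.diff(candidate) > 2)[0] + 1
        for run in np.split(candidate, splits):
            best = run[np.argmax(dens[run])]
            if dens[best] > 0.05 * dens.max():
                peaks.append(float(grid[best]))
    if not peaks:
        peaks = [float(grid[np.argmax(dens)])]
    return np.array(sorted(set(peaks)))


def _em_gaussian_mixture(
    x: np.ndarray, means: np.ndarray, cfg: CNConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """One EM run from the given means; returns params and the LL trace."""
    k = means.size
    means = means.copy()
    sigmas = np.full(k, max(x.std(ddof=1) / max(k, 1), cfg.sigma_floor))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(cfg.em_max_iter):
        log_comp = (
            -0.5 * ((x[None, :] - means[:, None]) / sigmas[:, None]) ** 2
            - np.log(sigmas[:, None] * math.sqrt(2 * math.pi))
            + np.log(weights[:, None])
        )
        m = log_comp.max(axis=0)
        log_total = m + np.log(np.exp(log_comp - m).sum(axis=0))
        ll = float(log_total.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_total)
        nk = resp.sum(axis=1)
        weights = nk / x.size
        means = (resp @ x) / np.maximum(nk, 1e-12)
        var = (resp @ x**2) / np.maximum(nk, 1e-12) - means**2
        sigmas = np.sqrt(np.maximum(var, cfg.sigma_floor**2))
        if ll - prev_ll < cfg.em_tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return means, sigmas, weights, trace


def fit_gaussian_peaks(
    ratios: np.ndarray, initial_peaks: Sequence[float], config: CNConfig | None = None
) -> list[CNPeak]:
    """EM refinement of a 1-D Gaussian mixture seeded at the wavelet peaks.

    Components whose weight drops below ``em_min_weight`` are pruned and
    EM restarted; sigmas are floored at ``sigma_floor``.  The
    log-likelihood is non-decreasing across iterations.
    """
    cfg = config or CNConfig()
    x = np.asarray(ratios, dtype=float)
    x = x[np.isfinite(x)]
    means = np.asarray(sorted(initial_peaks), dtype=float)
    if means.size == 0:
        raise ValueError("need at least one initial peak")

    while True:
        means, sigmas, weights, _ = _em_gaussian_mixture(x, means, cfg)
        if means.size > 1 and weights.min() < cfg.em_min_weight:
            keep = weights >= cfg.em_min_weight
            if not keep.any():
                keep[np.argmax(weights)] = True
            means = means[keep]
            continue
        break

    order = np.argsort(means)
    weights = weights / weights.sum()
    return [
        CNPeak(mean_ratio=float(means[i]), sigma=float(sigmas[i]), weight=float(weights[i]))
        for i in order
    ]


# ---------------------------------------------------------------------------
# HMM segmentation


def viterbi_path(obs: np.ndarray, peaks: Sequence[CNPeak], tau: float) -> np.ndarray:
    """Most probable state path for 1-D Gaussian-emission HMM.

    States are the peaks; the transition matrix has stay probability
    1 - tau and switches uniformly with total probability tau.
    """
    k = len(peaks)
    means = np.array([p.mean_ratio for p in peaks])
    sigmas = np.array([p.sigma for p in peaks])
    log_init = np.log(np.array([max(p.weight, 1e-12) for p in peaks]))
    if k == 1:
        return np.zeros(obs.size, dtype=int)
    log_stay = math.log(1 - tau)
    log_switch = math.log(tau / (k - 1))
    trans = np.full((k, k), log_switch)
    np.fill_diagonal(trans, log_stay)

    log_emit = (
        -0.5 * ((obs[:, None] - means[None, :]) / sigmas[None, :]) ** 2
        - np.log(sigmas[None, :] * math.sqrt(2 * math.pi))
    )
    n = obs.size
    delta = log_init + log_emit[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + trans
        back[t] = scores.argmax(axis=0)
        delta = scores.max(axis=0) + log_emit[t]
    path = np.empty(n, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def assign_states(
    track: DepthRatioTrack, peaks: Sequence[CNPeak], config: CNConfig | None = None
) -> np.ndarray:
    """Per-region Viterbi state indices (-1 for masked regions)."""
    cfg = config or CNConfig()
    if not peaks:
        raise ValueError("need at least one peak")
    chroms = np.array([r.chrom for r in track.regions])
    states = np.full(len(track.regions), -1, dtype=int)
    for chrom in dict.fromkeys(chroms):
        idx = np.where((chroms == chrom) & track.mask)[0]
        if idx.size == 0:
            continue
        states[idx] = viterbi_path(track.smoothed_ratio[idx], peaks, cfg.hmm_tau)
    return states


def segment_hmm(
    track: DepthRatioTrack, peaks: Sequence[CNPeak], config: CNConfig | None = None
) -> list[CNSegment]:
    """Viterbi state assignment per chromosome, merged into segments."""
    cfg = config or CNConfig()
    states = assign_states(track, peaks, cfg)
    chroms = np.array([r.chrom for r in track.regions])
    segments: list[CNSegment] = []
    for chrom in dict.fromkeys(chroms):
        idx = np.where((chroms == chrom) & track.mask)[0]
        if idx.size == 0:
            continue
        path = states[idx]
        start_j = 0
        for j in range(1, idx.size + 1):
            if j == idx.size or path[j] != path[start_j]:
                members = idx[start_j:j]
                segments.append(
                    CNSegment(
                        chrom=chrom,
                        start=track.regions[members[0]].start,
                        end=track.regions[members[-1]].end,
                        peak_id=int(path[start_j]),
                        mean_ratio=float(track.smoothed_ratio[members].mean()),
                        n_regions=int(members.size),
                    )
                )
                start_j = j
    return segments


# ---------------------------------------------------------------------------
# allelic imbalance and purity


def allelic_imbalance(
    segments: Sequence[CNSegment], het_snps: Sequence[HetSNP], config: CNConfig | None = None
) -> list[CNSegment]:
    """Fill mirrored BAF and allelic state from member heterozygous SNPs.

    mirrored BAF = mean over member SNPs of max(f, 1-f) where f is the
    tumor alt fraction; needs ``min_snps_per_segment`` SNPs, else stays
    absent.  State thresholds: imbalanced above 0.5 + margin, LOH above
    ``loh_mirrored_baf``; cnLOH is assigned later once integer CN is
    known (integer_cn == 2 with LOH-grade imbalance).
    """
    cfg = config or CNConfig()
    by_chrom: dict[str, list[HetSNP]] = {}
    for s in het_snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    out = []
    for seg in segments:
        members = [
            s
            for s in by_chrom.get(seg.chrom, [])
            if seg.start <= s.pos < seg.end and not math.isnan(s.tumor_alt_fraction)
        ]
        fs = [s.tumor_alt_fraction for s in members]
        seg = replace_segment(seg)
        seg.n_het_snps = len(fs)
        if members:
            seg.mean_snp_depth = float(
                np.mean([s.ref_count_tumor + s.alt_count_tumor for s in members])
            )
        if len(fs) >= cfg.min_snps_per_segment:
            m = float(np.mean([max(f, 1 - f) for f in fs]))
            seg.mirrored_baf = m
            if m >= cfg.loh_mirrored_baf:
                seg.allelic_state = "LOH"
            elif m > 0.5 + cfg.imbalance_margin:
                seg.allelic_state = "imbalanced"
            else:
                seg.allelic_state = "balanced"
        out.append(seg)
    return out


def replace_segment(seg: CNSegment) -> CNSegment:
    return CNSegment(**{f: getattr(seg, f) for f in seg.__dataclass_fields__})


def estimate_purity_from_loh(
    segments: Sequence[CNSegment], config: CNConfig | None = None
) -> Optional[PurityEstimate]:
    """Purity from allelic imbalance in LOH segments.

    For a hemizygous-deletion LOH segment (ratio below 1) the mirrored
    BAF is m = 1/(2-alpha), so alpha = 2 - 1/m; for copy-neutral LOH
    (ratio near 1) m = (1+alpha)/2, so alpha = 2m - 1.  Per-segment
    estimates are combined by a SNP-count-weighted median.
    """
    cfg = config or CNConfig()
    estimates: list[tuple[float, int]] = []
    for seg in segments:
        if seg.mirrored_baf is None or seg.n_het_snps < cfg.min_snps_per_segment:
            continue
        m = min(seg.mirrored_baf, 1.0 - 1e-9)
        if seg.mean_ratio < 0.9:
            # deletion-range ratio: any significant imbalance reflects the
            # lost allele, so treat as hemizygous-deletion LOH
            if seg.allelic_state not in ("LOH", "cnLOH", "imbalanced"):
                continue
            alpha = 2.0 - 1.0 / m
        else:
            # copy-neutral ratio: only a full LOH call is informative
            if seg.allelic_state not in ("LOH", "cnLOH"):
                continue
            alpha = 2.0 * m - 1.0
        if alpha > 0:
            estimates.append((min(alpha, 1.0), seg.n_het_snps))
    if not estimates:
        return None
    vals = np.array([e[0] for e in estimates])
    wts = np.array([e[1] for e in estimates], dtype=float)
    order = np.argsort(vals)
    cum = np.cumsum(wts[order])
    med = vals[order][np.searchsorted(cum, cum[-1] / 2.0)]
    alpha = float(np.clip(med, 0.01, 1.0))
    return PurityEstimate(alpha=alpha, method="loh_allelic_imbalance", support=int(wts.sum()))


def estimate_purity_from_vaf(
    somatic_vafs: Sequence[float], config: CNConfig | None = None
) -> Optional[PurityEstimate]:
    """Purity as twice the mode of the somatic-VAF density (clonal het)."""
    cfg = config or CNConfig()
    vafs = np.asarray([v for v in somatic_vafs if np.isfinite(v) and v > 0], dtype=float)
    if vafs.size < cfg.min_vaf_variants:
        return None
    grid = np.linspace(0.0, 1.0, 512)
    bw = max(0.9 * vafs.std(ddof=1) * vafs.size ** (-0.2), 0.01)
    dens = np.exp(-0.5 * ((grid[:, None] - vafs[None, :]) / bw) ** 2).sum(axis=1)
    mode = grid[int(np.argmax(dens))]
    alpha = float(np.clip(2.0 * mode, 0.01, 1.0))
    return PurityEstimate(alpha=alpha, method="vaf_distribution", support=int(vafs.size))


def purity_fallback_chain(
    segments: Sequence[CNSegment],
    somatic_vafs: Sequence[float] = (),
    config: CNConfig | None = None,
) -> PurityEstimate:
    """LOH-based estimate, then VAF-distribution, then the 0.2 default."""
    est = estimate_purity_from_loh(segments, config)
    if est is not None:
        return est
    est = estimate_purity_from_vaf(somatic_vafs, config)
    if est is not None:
        return est
    return PurityEstimate(alpha=DEFAULT_PURITY, method="default_constant", support=0)


# ---------------------------------------------------------------------------
# integer CN / purity lattice fit


def _expected_ratio(n: int, alpha: float) -> float:
    return (2.0 * (1.0 - alpha) + n * alpha) / 2.0


def _expected_mirrored_baf(n: int, b_minor: int, alpha: float, depth: float = 0.0) -> float:
    """Expected mean of max(f_hat, 1 - f_hat) over a segment's het SNPs.

    Without sampling noise this is max(f, 1 - f) for the two-population
    mixture allele fraction f; with binomial read sampling at the given
    depth, folding at 0.5 inflates the expectation (folded-normal mean),
    which matters most for balanced states, so the finite-depth
    correction is applied whenever a depth is supplied.
    """
    tot = 2.0 * (1.0 - alpha) + n * alpha
    if tot <= 0:
        return 0.5
    f = ((1.0 - alpha) + alpha * (n - b_minor)) / tot
    if depth <= 0:
        return max(f, 1.0 - f)
    d = f - 0.5
    s2 = f * (1.0 - f) / depth
    if s2 <= 0:
        return max(f, 1.0 - f)
    sd = math.sqrt(s2)
    from scipy.special import ndtr

    e_abs = sd * math.sqrt(2.0 / math.pi) * math.exp(-(d * d) / (2 * s2)) + d * (
        1.0 - 2.0 * float(ndtr(-d / sd))
    )
    return 0.5 + e_abs


def fit_integer_cn(
    peaks: Sequence[CNPeak],
    segments: Sequence[CNSegment],
    alpha_hint: Optional[float] = None,
    config: CNConfig | None = None,
    baf_penalty_weight: float = 0.5,
) -> tuple[PurityEstimate, list[CNSegment], list[CNPeak]]:
    """Grid search over purity jointly assigning integer CN to peaks.

    For each alpha on a 0.01 grid (restricted to hint +/- 0.2 when a
    hint is given), each peak gets the integer copy number whose
    expected ratio r(n) is nearest; the score is the weight-weighted sum
    of squared residuals plus a penalty comparing observed mirrored BAF
    of imbalanced/LOH segments with the best-matching allelic
    configuration at the assigned CN.  Ties break toward the hint, then
    toward smaller alpha.
    """
    cfg = config or CNConfig()
    if not peaks:
        raise ValueError("need at least one peak")
    alphas = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
    if alpha_hint is not None:
        alphas = alphas[(alphas >= alpha_hint - 0.2) & (alphas <= alpha_hint + 0.2)]
        if alphas.size == 0:
            alphas = np.array([round(min(max(alpha_hint, 0.05), 1.0), 2)])

    seg_by_peak: dict[int, list[CNSegment]] = {}
    for seg in segments:
        seg_by_peak.setdefault(seg.peak_id, []).append(seg)

    best = None
    for alpha in alphas:
        ns = []
        score = 0.0
        for p in peaks:
            resid = [(p.mean_ratio - _expected_ratio(n, alpha)) ** 2 for n in range(cfg.max_cn + 1)]
            n_best = int(np.argmin(resid))
            ns.append(n_best)
            score += p.weight * resid[n_best]
        # allelic-imbalance consistency of segments with measured BAF
        pen = 0.0
        wsum = 0.0
        for pid, segs in seg_by_peak.items():
            if pid >= len(ns):
                continue
            n = ns[pid]
            for seg in segs:
                if seg.mirrored_baf is None or seg.allelic_state == "balanced":
                    continue
                bafs = [
                    _expected_mirrored_baf(n, b, alpha, seg.mean_snp_depth)
                    for b in range(n // 2 + 1)
                ] or [0.5]
                pen += seg.n_het_snps * min((seg.mirrored_baf - eb) ** 2 for eb in bafs)
                wsum += seg.n_het_snps
        if wsum > 0:
            score += baf_penalty_weight * pen / wsum
        key = (score, abs(alpha - alpha_hint) if alpha_hint is not None else 0.0, alpha)
        if best is None or key < best[0]:
            best = (key, float(alpha), ns)

    _, alpha, ns = best
    out_peaks = [replace(p, assigned_cn=ns[i]) for i, p in enumerate(peaks)]
    out_segs = []
    for seg in segments:
        s = replace_segment(seg)
        s.integer_cn = ns[seg.peak_id] if seg.peak_id < len(ns) else None
        if s.integer_cn == 2 and s.allelic_state == "LOH":
            s.allelic_state = "cnLOH"
        out_segs.append(s)
    method = "loh_allelic_imbalance" if alpha_hint is not None else "model_fit"
    support = sum(s.n_het_snps for s in out_segs)
    return PurityEstimate(alpha=alpha, method=method, support=support), out_segs, out_peaks


def cna_frequency(
    sample_segments: Sequence[Sequence[CNSegment]],
    bins: Sequence[tuple[str, int, int]],
) -> "np.ndarray":
    """Per-bin gain/loss frequencies over samples.

    A sample counts as gain in a bin when any overlapping segment has
    integer CN > 2, and as loss when any overlapping segment has CN < 2
    or is copy-neutral LOH; loss takes precedence, so each sample
    contributes at most one category per bin.  Returns an array of shape
    (n_bins, 2) with columns (gain_freq, loss_freq).
    """
    n_samples = len(sample_segments)
    if n_samples == 0:
        raise ValueError("need at least one sample")
    out = np.zeros((len(bins), 2))
    for segs in sample_segments:
        for i, (chrom, start, end) in enumerate(bins):
            gain = loss = False
            for seg in segs:
                if seg.chrom != chrom or seg.end <= start or seg.start >= end:
                    continue
                if seg.integer_cn is None:
                    continue
                if seg.integer_cn < 2 or seg.allelic_state == "cnLOH":
                    loss = True
                elif seg.integer_cn > 2:
                    gain = True
            if loss:
                out[i, 1] += 1
            elif gain:
                out[i, 0] += 1
    return out / n_samples


def _lattice_peaks(alpha: float, sigma: float, max_cn: int) -> list[CNPeak]:
    k = max_cn + 1
    return [CNPeak(mean_ratio=max(_expected_ratio(n, alpha), 1e-3), sigma=sigma, weight=1.0 / k)
            for n in range(k)]


def _noise_sigma(track: DepthRatioTrack, floor: float = 0.03) -> float:
    """Robust per-region noise sd from first differences of the ratio."""
    chroms = np.array([r.chrom for r in track.regions])
    diffs = []
    for chrom in dict.fromkeys(chroms):
        idx = np.where((chroms == chrom) & track.mask)[0]
        if idx.size > 1:
            diffs.append(np.diff(track.smoothed_ratio[idx]))
    d = np.concatenate(diffs)
    mad = np.median(np.abs(d - np.median(d)))
    # the moving average correlates neighbours; first differences understate
    # the marginal sd, so scale back up by the window factor
    return max(1.4826 * mad / math.sqrt(2) * math.sqrt(5), floor)


def scan_purity_lattice(
    track: DepthRatioTrack,
    het_snps: Sequence[HetSNP],
    config: CNConfig | None = None,
    alpha_hint: Optional[float] = None,
    alpha_min: float = 0.2,
    baf_weight: float = 1.0,
) -> tuple[PurityEstimate, list[CNSegment]]:
    """Joint purity / integer-CN fit by scanning candidate purities.

    For each candidate alpha a lattice-state HMM (states at the expected
    ratios r(n), shared noise sigma) segments the track; the score is the
    mean squared ratio residual of regions to their assigned state plus a
    weighted allelic-imbalance consistency term comparing each
    informative segment's mirrored BAF with the closest allelic
    configuration at its assigned copy number.  Coarse 0.05 grid, then a
    fine 0.01 grid around the best candidate; ties break toward the hint
    and then toward smaller alpha.  Resolves copy-number states that are
    too close for density-based peak detection at low purity.
    """
    cfg = config or CNConfig()
    sigma = _noise_sigma(track, cfg.sigma_floor)
    ratios = track.smoothed_ratio
    lo = alpha_min if alpha_hint is None else max(alpha_min, alpha_hint - 0.2)
    hi = 1.0 if alpha_hint is None else min(1.0, alpha_hint + 0.2)

    def score(alpha: float) -> tuple[float, list[CNSegment], np.ndarray]:
        peaks = _lattice_peaks(alpha, sigma, cfg.max_cn)
        states = assign_states(track, peaks, cfg)
        segs = allelic_imbalance(segment_hmm(track, peaks, cfg), het_snps, cfg)
        expected = np.array([p.mean_ratio for p in peaks])
        # score segment means, not single regions: per-region residuals
        # reward an over-fine lattice, while segment means average out the
        # noise and expose the quantization misfit of a wrong lattice
        num = sum(s.n_regions * (s.mean_ratio - expected[s.peak_id]) ** 2 for s in segs)
        sse = float(num / max(sum(s.n_regions for s in segs), 1))
        pen = wsum = 0.0
        for seg in segs:
            if seg.mirrored_baf is None:
                continue
            n = seg.peak_id  # state index == copy number on the lattice
            bafs = [
                _expected_mirrored_baf(n, b, alpha, seg.mean_snp_depth)
                for b in range(n // 2 + 1)
            ] or [0.5]
            pen += seg.n_het_snps * min((seg.mirrored_baf - eb) ** 2 for eb in bafs)
            wsum += seg.n_het_snps
        total = sse + (baf_weight * pen / wsum if wsum > 0 else 0.0)
        return total, segs, states

    def best_of(grid) -> float:
        best_key, best_alpha = None, None
        for alpha in grid:
            total, _, _ = score(alpha)
            key = (total, abs(alpha - alpha_hint) if alpha_hint is not None else 0.0, alpha)
            if best_key is None or key < best_key:
                best_key, best_alpha = key, alpha
        return best_alpha

    coarse = np.round(np.arange(lo, hi + 1e-9, 0.05), 2)
    a0 = best_of(coarse)
    fine = np.round(np.arange(max(lo, a0 - 0.04), min(hi, a0 + 0.04) + 1e-9, 0.01), 2)
    alpha = best_of(fine)

    _, segs, _ = score(alpha)
    out = []
    for seg in segs:
        s = replace_segment(seg)
        s.integer_cn = seg.peak_id
        if s.integer_cn == 2 and s.allelic_state == "LOH":
            s.allelic_state = "cnLOH"
        out.append(s)
    support = sum(s.n_het_snps for s in out if s.mirrored_baf is not None)
    return PurityEstimate(alpha=float(alpha), method="loh_allelic_imbalance", support=support), out


# ---------------------------------------------------------------------------
# end-to-end driver


def run_cn_pipeline(
    regions: Sequence[RegionDepth],
    het_snps: Sequence[HetSNP] = (),
    somatic_vafs: Sequence[float] = (),
    config: CNConfig | None = None,
    alpha_override: Optional[float] = None,
) -> dict:
    """Full engine: ratios -> peaks -> EM -> HMM -> imbalance -> purity/CN."""
    cfg = config or CNConfig()
    track = compute_depth_ratio(regions, cfg)
    candidates = detect_peaks_wavelet(track, cfg)
    peaks = fit_gaussian_peaks(track.usable_ratios, candidates, cfg)
    segments = segment_hmm(track, peaks, cfg)
    segments = allelic_imbalance(segments, het_snps, cfg)
    purity0 = purity_fallback_chain(segments, somatic_vafs, cfg)
    has_baf = any(s.mirrored_baf is not None for s in segments)

    if alpha_override is not None:
        purity = PurityEstimate(alpha=alpha_override, method="override", support=0)
        _, segments, peaks = fit_integer_cn(peaks, segments, alpha_hint=alpha_override, config=cfg)
    elif has_baf:
        hint = purity0.alpha if purity0.method == "loh_allelic_imbalance" else None
        purity, segments = scan_purity_lattice(track, het_snps, cfg, alpha_hint=hint)
        if purity0.method == "vaf_distribution":
            purity = PurityEstimate(purity.alpha, "vaf_distribution", purity0.support)
    else:
        # no allelic information: VAF-based alpha or the stated 0.2 default
        purity = purity0
        _, segments, peaks = fit_integer_cn(peaks, segments, alpha_hint=purity.alpha, config=cfg)
    return {
        "track": track,
        "peaks": peaks,
        "segments": segments,
        "purity": purity,
    }
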