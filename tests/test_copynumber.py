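"""Tests for the depth-ratio copy-number and purity engine."""

import itertools
import math

import numpy as np
import pytest

from glioma_omics import copynumber as cn
from glioma_omics import synthetic
from glioma_omics.copynumber import (
    CNConfig,
    CNPeak,
    CNSegment,
    HetSNP,
    RegionDepth,
    _em_gaussian_mixture,
    _expected_mirrored_baf,
    viterbi_path,
)


def make_regions(depth_t, depth_n, gc=None, chrom="chr1"):
    n = len(depth_t)
    gc = gc if gc is not None else [0.5] * n
    return [
        RegionDepth(chrom, 1000 * i, 1000 * i + 500, gc[i], float(depth_t[i]), float(depth_n[i]))
        for i in range(n)
    ]


def region_cn_concordance(regions, segments, true_cn):
    by_key = {}
    for idx, r in enumerate(regions):
        by_key.setdefault(r.chrom, []).append((r.start, idx))
    assigned = np.full(len(regions), -1)
    for s in segments:
        for start, idx in by_key[s.chrom]:
            if s.start <= start < s.end:
                assigned[idx] = s.integer_cn
    return (assigned == true_cn).mean()


class TestDepthRatio:
    def test_identical_depths_give_unit_ratio(self):
        regions = make_regions([100.0] * 60, [100.0] * 60)
        track = cn.compute_depth_ratio(regions)
        assert np.allclose(track.smoothed_ratio, 1.0)

    def test_doubled_tumor_depth(self):
        regions = make_regions([200.0] * 60, [100.0] * 60)
        track = cn.compute_depth_ratio(regions)
        # library normalization absorbs the global factor; GC correction
        # recenters at the genome median, so a uniform doubling is ratio 1
        assert np.allclose(track.raw_ratio, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        dn = rng.poisson(100, 80).astype(float) + 1
        dt = rng.poisson(100, 80).astype(float) + 1
        t1 = cn.compute_depth_ratio(make_regions(dt, dn))
        t2 = cn.compute_depth_ratio(make_regions(dt * 7.3, dn))
        assert np.allclose(t1.smoothed_ratio, t2.smoothed_ratio)

    def test_gc_bias_removed(self):
        # plant a sinusoidal GC-dependent bias in the tumor only
        rng = np.random.default_rng(1)
        n = 2000
        gc = np.clip(rng.normal(0.45, 0.1, n), 0.2, 0.8)
        bias = 1.0 + 0.3 * np.sin(2 * math.pi * (gc - 0.2) / 0.6)
        dn = rng.poisson(100, n).astype(float) + 1
        dt = rng.poisson(100 * bias).astype(float) + 1
        track = cn.compute_depth_ratio(make_regions(dt, dn, gc=list(gc)))
        bins = np.clip((gc * 40).astype(int), 0, 39)
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() < 20:
                continue
            assert abs(np.median(track.gc_corrected_ratio[sel]) - 1.0) < 0.02

    def test_low_depth_regions_masked(self):
        regions = make_regions([100.0] * 59 + [100.0], [100.0] * 59 + [1.0])
        track = cn.compute_depth_ratio(regions)
        assert not track.mask[-1]
        assert track.mask[:-1].all()

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError):
            cn.compute_depth_ratio(make_regions([10.0] * 5, [1.0] * 5))


class TestPeakDetection:
    def test_single_state_genome(self):
        rng = np.random.default_rng(2)
        peaks = cn.detect_peaks_wavelet(rng.normal(1.0, 0.02, 500))
        assert peaks.size == 1
        assert abs(peaks[0] - 1.0) < 0.02

    def test_three_component_mixture(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([
            rng.normal(0.7, 0.03, 400), rng.normal(1.0, 0.03, 1200), rng.normal(1.3, 0.03, 400)
        ])
        peaks = cn.detect_peaks_wavelet(x)
        assert peaks.size == 3
        for got, want in zip(peaks, [0.7, 1.0, 1.3]):
            assert abs(got - want) < 0.03

    def test_ascending_and_unique(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0.8, 0.04, 500), rng.normal(1.4, 0.04, 500)])
        peaks = cn.detect_peaks_wavelet(x)
        assert np.all(np.diff(peaks) > 0)

    def test_too_few_ratios_rejected(self):
        with pytest.raises(ValueError):
            cn.detect_peaks_wavelet(np.ones(30))


class TestGaussianEM:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.normal(1.2, 0.05, 3000)
        peaks = cn.fit_gaussian_peaks(x, [1.1])
        assert len(peaks) == 1
        se = 0.05 / math.sqrt(3000)
        assert abs(peaks[0].mean_ratio - 1.2) < 2 * se + 1e-3

    def test_three_component_weights(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([
            rng.normal(0.7, 0.03, 400), rng.normal(1.0, 0.03, 1200), rng.normal(1.3, 0.03, 400)
        ])
        peaks = cn.fit_gaussian_peaks(x, [0.7, 1.0, 1.3])
        assert len(peaks) == 3
        for p, w in zip(peaks, [0.2, 0.6, 0.2]):
            assert abs(p.weight - w) < 0.05
        assert abs(sum(p.weight for p in peaks) - 1.0) < 1e-6

    def test_loglik_monotone(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.8, 0.05, 300), rng.normal(1.2, 0.05, 300)])
        _, _, _, trace = _em_gaussian_mixture(x, np.array([0.9, 1.1]), CNConfig())
        assert np.all(np.diff(trace) >= -1e-8)

    def test_sigma_floored(self):
        x = np.full(100, 1.0)
        peaks = cn.fit_gaussian_peaks(x, [1.0])
        assert peaks[0].sigma >= CNConfig().sigma_floor


class TestViterbi:
    def brute_force(self, obs, peaks, tau):
        k = len(peaks)
        best_lp, best_path = -np.inf, None
        for path in itertools.product(range(k), repeat=len(obs)):
            lp = math.log(max(peaks[path[0]].weight, 1e-12))
            for t, s in enumerate(path):
                mu, sd = peaks[s].mean_ratio, peaks[s].sigma
                lp += -0.5 * ((obs[t] - mu) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))
                if t > 0:
                    lp += math.log(1 - tau) if path[t] == path[t - 1] else math.log(tau / (k - 1))
            if lp > best_lp:
                best_lp, best_path = lp, path
        return np.array(best_path)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(8)
        for trial in range(12):
            k = int(rng.integers(2, 4))
            n = int(rng.integers(3, 13))
            peaks = [
                CNPeak(mean_ratio=0.6 + 0.3 * i, sigma=float(rng.uniform(0.05, 0.2)),
                       weight=1.0 / k)
                for i in range(k)
            ]
            obs = rng.uniform(0.4, 1.8, n)
            got = viterbi_path(obs, peaks, tau=1e-3)
            want = self.brute_force(obs, peaks, 1e-3)
            assert np.array_equal(got, want)

    def test_single_peak_single_segment_per_chromosome(self):
        rng = np.random.default_rng(9)
        regions = make_regions(rng.poisson(100, 60), rng.poisson(100, 60), chrom="chr1")
        regions += make_regions(rng.poisson(100, 60), rng.poisson(100, 60), chrom="chr2")
        track = cn.compute_depth_ratio(regions)
        peaks = [CNPeak(mean_ratio=1.0, sigma=0.1, weight=1.0)]
        segs = cn.segment_hmm(track, peaks)
        assert len(segs) == 2
        assert {s.chrom for s in segs} == {"chr1", "chr2"}

    def test_recovers_planted_segments(self):
        # 6 segments over 2000 regions, steps >= 0.25, noise sd 0.05
        rng = np.random.default_rng(10)
        levels = [1.0, 1.5, 1.0, 0.75, 1.25, 1.0]
        lengths = [400, 300, 350, 300, 250, 400]
        truth_state = np.concatenate([np.full(l, v) for v, l in zip(levels, lengths)])
        obs = truth_state + rng.normal(0, 0.05, truth_state.size)
        peaks = [CNPeak(mean_ratio=v, sigma=0.05, weight=0.25) for v in sorted(set(levels))]
        path = viterbi_path(obs, peaks, tau=1e-4)
        means = np.array([p.mean_ratio for p in peaks])
        assert (means[path] == truth_state).mean() >= 0.95
        # every true breakpoint matched within +/- 2 regions
        true_bp = np.cumsum(lengths)[:-1]
        got_bp = np.where(np.diff(path) != 0)[0] + 1
        for bp in true_bp:
            assert np.min(np.abs(got_bp - bp)) <= 2


class TestAllelicImbalance:
    def test_expected_mirrored_baf_algebra(self):
        # pure tumor hemizygous deletion: only one allele remains
        assert _expected_mirrored_baf(1, 0, 1.0) == pytest.approx(1.0)
        # alpha=0.5 hemizygous deletion: 1/(2-alpha)
        assert _expected_mirrored_baf(1, 0, 0.5) == pytest.approx(1 / 1.5, abs=1e-9)
        # alpha=0.5 cnLOH: (1+alpha)/2
        assert _expected_mirrored_baf(2, 0, 0.5) == pytest.approx(0.75)

    def _segment_with_snps(self, m_target, n_snps=40, depth=200):
        snps = []
        alt = int(round(m_target * depth))
        for i in range(n_snps):
            snps.append(HetSNP("chr1", 100 + i, depth - alt, alt, depth // 2, depth // 2))
        seg = CNSegment("chr1", 0, 10_000, peak_id=0, mean_ratio=0.7, n_regions=50)
        return seg, snps

    def test_loh_annotation(self):
        seg, snps = self._segment_with_snps(0.8)
        (out,) = cn.allelic_imbalance([seg], snps)
        assert out.allelic_state == "LOH"
        assert out.mirrored_baf == pytest.approx(0.8)
        assert out.n_het_snps == 40

    def test_balanced_annotation_and_min_snps(self):
        seg, snps = self._segment_with_snps(0.5, n_snps=40)
        (out,) = cn.allelic_imbalance([seg], snps)
        assert out.allelic_state == "balanced"
        seg2, snps2 = self._segment_with_snps(0.9, n_snps=5)
        (out2,) = cn.allelic_imbalance([seg2], snps2)
        assert out2.mirrored_baf is None  # too few SNPs

    def test_purity_inversion_from_loh(self):
        # m = 1.0 hemizygous deletion -> alpha = 1.0
        seg, snps = self._segment_with_snps(1.0)
        (out,) = cn.allelic_imbalance([seg], snps)
        est = cn.estimate_purity_from_loh([out])
        assert est.alpha == pytest.approx(1.0, abs=0.01)
        # m = 0.667 -> alpha ~ 0.5
        seg, snps = self._segment_with_snps(2 / 3)
        (out,) = cn.allelic_imbalance([seg], snps)
        est = cn.estimate_purity_from_loh([out])
        assert est.alpha == pytest.approx(0.5, abs=0.01)

    def test_purity_recovery_binomial_snps(self):
        rng = np.random.default_rng(11)
        alpha = 0.6
        f = 1 / (2 - alpha)  # major allele fraction in hemizygous-deletion LOH
        snps = []
        for i in range(200):
            d = rng.poisson(100)
            a = rng.binomial(d, f)
            snps.append(HetSNP("chr1", i * 10, int(d - a), int(a), 50, 50))
        seg = CNSegment("chr1", 0, 3000, peak_id=0, mean_ratio=0.7, n_regions=100)
        (out,) = cn.allelic_imbalance([seg], snps)
        est = cn.estimate_purity_from_loh([out])
        assert abs(est.alpha - alpha) <= 0.05


class TestPurityFromVaf:
    def test_clonal_het_pure(self):
        rng = np.random.default_rng(12)
        vafs = rng.normal(0.5, 0.01, 100)
        assert cn.estimate_purity_from_vaf(vafs).alpha == pytest.approx(1.0, abs=0.02)

    def test_half_purity(self):
        rng = np.random.default_rng(13)
        vafs = rng.normal(0.25, 0.01, 100)
        assert cn.estimate_purity_from_vaf(vafs).alpha == pytest.approx(0.5, abs=0.05)

    def test_binomial_simulation(self):
        rng = np.random.default_rng(14)
        alpha = 0.4
        vafs = rng.binomial(120, alpha / 2, 80) / 120
        est = cn.estimate_purity_from_vaf(vafs)
        assert abs(est.alpha - alpha) <= 0.08

    def test_too_few_variants(self):
        assert cn.estimate_purity_from_vaf([0.3, 0.2]) is None


class TestFallbackChain:
    def test_default_constant(self):
        est = cn.purity_fallback_chain([], [])
        assert est.alpha == 0.2
        assert est.method == "default_constant"

    def test_vaf_when_no_loh(self):
        rng = np.random.default_rng(15)
        vafs = rng.normal(0.25, 0.02, 100)
        est = cn.purity_fallback_chain([], vafs)
        assert est.method == "vaf_distribution"

    def test_loh_takes_precedence(self):
        snps = [HetSNP("chr1", i, 40, 160, 50, 50) for i in range(20)]
        seg = CNSegment("chr1", 0, 1000, peak_id=0, mean_ratio=0.7, n_regions=30)
        (seg,) = cn.allelic_imbalance([seg], snps)
        est = cn.purity_fallback_chain([seg], [0.25] * 100)
        assert est.method == "loh_allelic_imbalance"


class TestIntegerCNFit:
    def test_exact_lattice_pure(self):
        peaks = [CNPeak(1.0, 0.03, 0.5), CNPeak(1.5, 0.03, 0.5)]
        est, _, out_peaks = cn.fit_integer_cn(peaks, [], alpha_hint=1.0)
        assert est.alpha == pytest.approx(1.0)
        assert [p.assigned_cn for p in out_peaks] == [2, 3]

    def test_half_purity_lattice(self):
        peaks = [CNPeak(1.0, 0.03, 0.5), CNPeak(1.25, 0.03, 0.5)]
        est, _, out_peaks = cn.fit_integer_cn(peaks, [], alpha_hint=0.5)
        assert est.alpha == pytest.approx(0.5, abs=0.01)
        assert [p.assigned_cn for p in out_peaks] == [2, 3]

    def test_pure_tumor_maps_ratio_to_2r(self):
        for r in (0.5, 1.0, 1.5, 2.0):
            peaks = [CNPeak(1.0, 0.02, 0.5), CNPeak(r, 0.02, 0.5)]
            _, _, out = cn.fit_integer_cn(peaks, [], alpha_hint=1.0)
            assert out[-1].assigned_cn == int(2 * r) or r == 1.0


class TestCnaFrequency:
    BINS = [("chr1", 0, 1000), ("chr1", 1000, 2000)]

    def seg(self, start, end, cn_val, state="balanced"):
        return CNSegment("chr1", start, end, 0, 1.0, 10, integer_cn=cn_val, allelic_state=state)

    def test_diploid_genome_all_zero(self):
        freq = cn.cna_frequency([[self.seg(0, 2000, 2)]], self.BINS)
        assert np.allclose(freq, 0.0)

    def test_half_samples_deleted(self):
        samples = [[self.seg(0, 2000, 1)], [self.seg(0, 2000, 1)],
                   [self.seg(0, 2000, 2)], [self.seg(0, 2000, 2)]]
        freq = cn.cna_frequency(samples, self.BINS)
        assert np.allclose(freq[:, 1], 0.5)
        assert np.allclose(freq[:, 0], 0.0)

    def test_cnloh_counts_as_loss(self):
        freq = cn.cna_frequency([[self.seg(0, 2000, 2, state="cnLOH")]], self.BINS)
        assert np.allclose(freq[:, 1], 1.0)
        assert np.allclose(freq[:, 0], 0.0)


class TestEndToEnd:
    @pytest.mark.parametrize("alpha", [0.5, 0.9])
    def test_purity_and_cn_recovery(self, alpha):
        regions, snps, truth = synthetic.simulate_tumor_exome(alpha=alpha, seed=41)
        res = cn.run_cn_pipeline(regions, snps)
        assert abs(res["purity"].alpha - alpha) <= 0.05
        assert region_cn_concordance(regions, res["segments"], truth["cn_per_region"]) >= 0.95

    def test_low_purity_never_crashes(self):
        regions, snps, truth = synthetic.simulate_tumor_exome(alpha=0.12, seed=42)
        res = cn.run_cn_pipeline(regions, snps)
        assert 0 < res["purity"].alpha <= 1
        assert res["purity"].method in {
            "loh_allelic_imbalance", "vaf_distribution", "default_constant"
        }

    def test_generator_null_genome(self):
        profile = [synthetic.CNSegmentSpec(2000, 2, "balanced")]
        regions, snps, truth = synthetic.simulate_tumor_exome(
            alpha=1.0, cn_profile=profile, seed=43
        )
        track = cn.compute_depth_ratio(regions)
        assert abs(np.mean(track.usable_ratios) - 1.0) <= 0.02

    def test_generator_mirrored_baf_algebra(self):
        profile = [synthetic.CNSegmentSpec(2000, 1, "LOH")]
        regions, snps, truth = synthetic.simulate_tumor_exome(
            alpha=0.5, cn_profile=profile, seed=44
        )
        m = np.mean([
            max(s.tumor_alt_fraction, 1 - s.tumor_alt_fraction) for s in snps
        ])
        # expectation 1/(2-alpha) = 0.667 plus a small folding inflation
        assert abs(m - 2 / 3) <= 0.015
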