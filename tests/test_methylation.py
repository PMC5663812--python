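"""Tests for beta-value processing, clustering and differential methylation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from glioma_omics import methylation as meth
from glioma_omics import synthetic


class TestBetaFormula:
    def test_exact_values(self):
        assert meth.beta_from_intensities(0, 0) == 0.0
        assert meth.beta_from_intensities(900, 0) == pytest.approx(0.9)
        assert meth.beta_from_intensities(1000, 1000) == pytest.approx(1000 / 2100)

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m, u = rng.uniform(0, 1e5, 2)
            b = meth.beta_from_intensities(m, u)
            assert 0 <= b < 1
            assert meth.beta_from_intensities(m + 100, u) > b

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            meth.beta_from_intensities(-1, 10)


def small_annotation():
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(10)],
        "chrom": ["chr1"] * 7 + ["chrX", "chrX", "chr2"],
        "pos": list(range(100, 800, 100)) + [10, 20, 500],
        "gene": ["G1"] * 3 + ["G2"] * 2 + ["", ""] + ["", "", ""],
        "tss_distance": [0, 700, 1500, -1200, 1501, 5000, 9000, 0, 0, 3000],
        "snp_associated": [False] * 9 + [True],
    })


class TestProbeFiltering:
    def test_xy_and_snp_removed(self):
        ann = small_annotation()
        mat = pd.DataFrame(np.random.default_rng(1).uniform(size=(10, 4)),
                           index=ann["probe_id"], columns=list("abcd"))
        out = meth.filter_probes(mat, ann)
        assert len(out) == 7  # 2 chrX + 1 SNP dropped
        assert "p7" not in out.index and "p9" not in out.index

    def test_platform_intersection(self):
        ann = small_annotation()
        mat = pd.DataFrame(np.random.default_rng(2).uniform(size=(10, 4)),
                           index=ann["probe_id"], columns=list("abcd"))
        out = meth.filter_probes(mat, ann, reference_platform_sets=[{"p0", "p1", "p7"}])
        assert set(out.index) == {"p0", "p1"}

    def test_idempotent(self):
        ann = small_annotation()
        mat = pd.DataFrame(np.random.default_rng(3).uniform(size=(10, 4)),
                           index=ann["probe_id"], columns=list("abcd"))
        once = meth.filter_probes(mat, ann)
        twice = meth.filter_probes(once, ann)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_intersection_is_error(self):
        ann = small_annotation()
        mat = pd.DataFrame(np.zeros((10, 4)), index=ann["probe_id"], columns=list("abcd"))
        with pytest.raises(ValueError):
            meth.filter_probes(mat, ann, reference_platform_sets=[{"nonexistent"}])


class TestTopVariable:
    def test_varying_probe_wins(self):
        mat = pd.DataFrame({"s1": [0.5, 0.1], "s2": [0.5, 0.9]}, index=["flat", "var"])
        assert list(meth.select_top_variable(mat, 1).index) == ["var"]

    def test_identity_at_full_k(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.uniform(size=(20, 5)), index=[f"p{i}" for i in range(20)])
        assert set(meth.select_top_variable(mat, 20).index) == set(mat.index)

    def test_planted_high_variance_set(self):
        rng = np.random.default_rng(5)
        n_null, n_planted = 4950, 50
        null = rng.normal(0.5, 0.01, size=(n_null, 30))
        planted = rng.normal(0.5, 0.05, size=(n_planted, 30))
        mat = pd.DataFrame(np.vstack([null, planted]),
                           index=[f"n{i}" for i in range(n_null)] + [f"v{i}" for i in range(n_planted)])
        top = meth.select_top_variable(mat.clip(0, 1), 50)
        assert all(p.startswith("v") for p in top.index)

    def test_commutes_with_sample_permutation(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.uniform(size=(30, 8)), index=[f"p{i}" for i in range(30)],
                           columns=[f"s{i}" for i in range(8)])
        a = meth.select_top_variable(mat, 10)
        b = meth.select_top_variable(mat[rng.permutation(mat.columns)], 10)
        assert list(a.index) == list(b.index)

    def test_bad_k(self):
        mat = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            meth.select_top_variable(mat, 0)


class TestConsensusClustering:
    def test_k1_trivial(self):
        rng = np.random.default_rng(7)
        mat = pd.DataFrame(rng.uniform(size=(50, 8)), columns=[f"s{i}" for i in range(8)])
        consensus, labels = meth.consensus_kmeans(mat, k=1)
        assert (consensus.to_numpy() == 1.0).all()
        assert labels.nunique() == 1

    def test_planted_six_clusters_perfect_recovery(self):
        beta, ann, truth = synthetic.simulate_beta_matrix(
            n_clusters=6, samples_per_cluster=10, n_probes=800, noise_sd=0.03, seed=8
        )
        filtered = meth.filter_probes(beta, ann)
        top = meth.select_top_variable(filtered, 400)
        _, labels = meth.consensus_kmeans(top, k=6, resample_reps=50, seed=8)
        assert adjusted_rand_score(truth["cluster_labels"], labels.to_numpy()) == 1.0

    def test_consensus_matrix_contract(self):
        rng = np.random.default_rng(9)
        mat = pd.DataFrame(rng.uniform(size=(40, 12)), columns=[f"s{i}" for i in range(12)])
        consensus, _ = meth.consensus_kmeans(mat, k=3, resample_reps=20, seed=9)
        c = consensus.to_numpy()
        assert np.allclose(c, c.T)
        assert (c >= 0).all() and (c <= 1).all()
        assert np.allclose(np.diag(c), 1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(10)
        mat = pd.DataFrame(rng.uniform(size=(60, 15)), columns=[f"s{i}" for i in range(15)])
        c1, l1 = meth.consensus_kmeans(mat, k=4, resample_reps=15, seed=123)
        c2, l2 = meth.consensus_kmeans(mat, k=4, resample_reps=15, seed=123)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)

    def test_k_exceeding_samples(self):
        mat = pd.DataFrame(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            meth.consensus_kmeans(mat, k=6)


class TestPromoterBeta:
    def test_single_probe_and_mean(self):
        ann = pd.DataFrame({
            "probe_id": ["a", "b", "c", "d"],
            "chrom": ["chr1"] * 4,
            "pos": [1, 2, 3, 4],
            "gene": ["G", "G", "G", "H"],
            "tss_distance": [0, 100, -200, 0],
            "snp_associated": [False] * 4,
        })
        mat = pd.DataFrame({"s1": [0.2, 0.4, 0.6, 0.4]}, index=["a", "b", "c", "d"])
        pb = meth.promoter_beta(mat, ann)
        assert pb.loc["G", "s1"] == pytest.approx(0.4)
        assert pb.loc["H", "s1"] == pytest.approx(0.4)

    def test_window_boundary_inclusive(self):
        ann = pd.DataFrame({
            "probe_id": ["in", "out"],
            "chrom": ["chr1", "chr1"],
            "pos": [1, 2],
            "gene": ["G", "G"],
            "tss_distance": [1500, 1501],
            "snp_associated": [False, False],
        })
        mat = pd.DataFrame({"s1": [0.3, 0.9]}, index=["in", "out"])
        pb = meth.promoter_beta(mat, ann)
        assert pb.loc["G", "s1"] == pytest.approx(0.3)


class TestDifferentialPromoters:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0.2, 0.8, size=(50, 6))
        pb = pd.DataFrame(np.hstack([vals, vals]), index=[f"G{i}" for i in range(50)],
                          columns=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)])
        res = meth.differential_promoters(pb, [f"a{i}" for i in range(6)],
                                          [f"b{i}" for i in range(6)])
        assert not res["significant"].any()

    def test_both_criteria_required(self):
        # large difference but tiny n with high variance -> q too large
        pb = pd.DataFrame(
            {"a1": [0.9, 0.5], "a2": [0.1, 0.5], "b1": [0.5, 0.5], "b2": [0.52, 0.5]},
            index=["bigdiff", "null"],
        )
        res = meth.differential_promoters(pb, ["a1", "a2"], ["b1", "b2"])
        row = res[res["gene"] == "bigdiff"].iloc[0]
        assert abs(row["difference"]) > 0.2 or row["q_value"] >= 0.01
        assert not row["significant"] or (row["q_value"] < 0.01 and abs(row["difference"]) > 0.2)

    def test_swapped_groups_negate_difference(self):
        rng = np.random.default_rng(12)
        pb = pd.DataFrame(rng.uniform(size=(30, 10)), index=[f"G{i}" for i in range(30)],
                          columns=[f"s{i}" for i in range(10)])
        g1, g2 = [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        r12 = meth.differential_promoters(pb, g1, g2).set_index("gene")
        r21 = meth.differential_promoters(pb, g2, g1).set_index("gene")
        assert np.allclose(r12["difference"], -r21.loc[r12.index, "difference"])
        assert np.allclose(r12["p_value"], r21.loc[r12.index, "p_value"])
        assert np.allclose(r12["q_value"], r21.loc[r12.index, "q_value"])

    def test_planted_recovery_study_group_sizes(self):
        beta, ann, truth = synthetic.simulate_beta_matrix(
            n_genes=2000, n_probes=6200, probes_per_gene=3, n_differential_genes=40,
            delta_beta=0.35, noise_sd=0.05, group_split=(18, 123), n_xy_probes=0,
            n_snp_probes=0, seed=13,
        )
        pb = meth.promoter_beta(beta, ann)
        groups = truth["sample_groups"]
        g1 = list(beta.columns[groups == 0])
        g2 = list(beta.columns[groups == 1])
        res = meth.differential_promoters(pb, g1, g2)
        called = set(res.loc[res["significant"], "gene"])
        planted = set(truth["differential_genes"])
        assert len(called & planted) >= 36
        assert len(called - planted) <= 2


class TestStratification:
    def test_threshold_boundaries(self):
        pb = pd.DataFrame({"s1": [0.49], "s2": [0.50], "s3": [0.6999], "s4": [0.70]},
                          index=["SOX10"])
        strata = meth.stratify_by_promoter(pb, "SOX10")
        assert strata["s1"] == "hypo"
        assert strata["s2"] == "intermediate"
        assert strata["s3"] == "intermediate"
        assert strata["s4"] == "hyper"

    def test_all_zero_hypo(self):
        pb = pd.DataFrame({f"s{i}": [0.0] for i in range(5)}, index=["G"])
        assert (meth.stratify_by_promoter(pb, "G") == "hypo").all()

    def test_missing_anchor(self):
        pb = pd.DataFrame({"s1": [0.5]}, index=["G"])
        with pytest.raises(KeyError):
            meth.stratify_by_promoter(pb, "ABSENT")


class TestDistalSelection:
    def build(self, seed=14):
        rng = np.random.default_rng(seed)
        n_null, n_planted, n_promoter = 3000, 30, 50
        n_hypo, n_hyper = 40, 60
        rows, ids = [], []
        ann_rows = []
        pid = 0
        for group, n, diff in [("null", n_null, 0.0), ("planted", n_planted, -0.4)]:
            for _ in range(n):
                base = rng.uniform(0.4, 0.6)
                hypo_vals = np.clip(base + diff + rng.normal(0, 0.05, n_hypo), 0, 1)
                hyper_vals = np.clip(base + rng.normal(0, 0.05, n_hyper), 0, 1)
                rows.append(np.concatenate([hypo_vals, hyper_vals]))
                ids.append(f"{group}{pid}")
                ann_rows.append(dict(probe_id=f"{group}{pid}", chrom="chr1", pos=1000 * pid + 600,
                                     gene="", tss_distance=5000, snp_associated=False))
                pid += 1
        for _ in range(n_promoter):  # promoter probes with a huge shift: must be excluded
            rows.append(np.concatenate([np.full(n_hypo, 0.1), np.full(n_hyper, 0.9)]))
            ids.append(f"prom{pid}")
            ann_rows.append(dict(probe_id=f"prom{pid}", chrom="chr1", pos=1000 * pid,
                                 gene="G", tss_distance=1200, snp_associated=False))
            pid += 1
        samples = [f"h{i}" for i in range(n_hypo)] + [f"H{i}" for i in range(n_hyper)]
        mat = pd.DataFrame(rows, index=ids, columns=samples)
        ann = pd.DataFrame(ann_rows)
        return mat, ann, samples[:n_hypo], samples[n_hypo:]

    def test_planted_distal_probes_selected(self):
        mat, ann, hypo, hyper = self.build()
        selected, bed = meth.select_distal_hypo_probes(mat, ann, hypo, hyper)
        got = set(selected["probe_id"])
        assert all(p.startswith("planted") for p in got - {""}), got - {""}
        assert sum(1 for p in got if p.startswith("planted")) == 30
        assert sum(1 for p in got if p.startswith("null")) <= 1
        assert not any(p.startswith("prom") for p in got)

    def test_window_clamped_at_chromosome_start(self):
        mat = pd.DataFrame({"h1": [0.0], "h2": [0.0], "H1": [0.9], "H2": [0.9]}, index=["p"])
        ann = pd.DataFrame([dict(probe_id="p", chrom="chr1", pos=250, gene="",
                                 tss_distance=9000, snp_associated=False)])
        _, bed = meth.select_distal_hypo_probes(mat, ann, ["h1", "h2"], ["H1", "H2"],
                                                q_max=1.0, diff_max=-0.25)
        assert bed.iloc[0]["start"] == 0
        assert bed.iloc[0]["end"] == 750
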