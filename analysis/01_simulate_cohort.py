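#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes, under results/data/: tumor/normal capture-region depths and
het-SNP allele counts for a grid of tumor purities, a somatic-candidate
table with planted artifacts, an Infinium-style beta matrix with six
planted subtypes, a two-group beta matrix with planted differential
promoters, junction reads with designed true fusions and decoys, and a
two-arm survival table.  Every file is reproducible from the seed.
"""

import json
from pathlib import Path

import pandas as pd

from glioma_omics import io as gio
from glioma_omics import synthetic

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for alpha in (0.3, 0.5, 0.7, 0.9):
        tag = f"alpha{int(alpha * 100):02d}"
        regions, snps, truth = synthetic.simulate_tumor_exome(alpha=alpha, seed=SEED)
        gio.write_region_table(regions, OUT / f"exome_{tag}.regions.tsv")
        gio.write_snp_table(snps, OUT / f"exome_{tag}.snps.tsv")
        pd.DataFrame(truth["segments"]).to_csv(
            OUT / f"exome_{tag}.truth_segments.tsv", sep="\t", index=False
        )
        print(f"exome {tag}: {len(regions)} regions, {len(snps)} het SNPs")

    cands, truth_var = synthetic.simulate_somatic_candidates(
        alpha=0.6, n_true=1000, n_artifacts=1000, seed=SEED
    )
    cands.to_csv(OUT / "somatic_candidates.tsv", sep="\t", index=False)
    truth_var.to_csv(OUT / "somatic_truth.tsv", sep="\t", index=False)
    print(f"somatic candidates: {len(cands)} (1000 true, 1000 artifacts)")

    beta, ann, truth_clust = synthetic.simulate_beta_matrix(
        n_clusters=6, samples_per_cluster=10, n_probes=800, seed=SEED
    )
    gio.write_beta_csv(beta, OUT / "beta_subtypes.csv")
    ann.to_csv(OUT / "beta_subtypes.annotation.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": beta.columns, "cluster": truth_clust["cluster_labels"]}).to_csv(
        OUT / "beta_subtypes.truth.tsv", sep="\t", index=False
    )
    print(f"subtype beta matrix: {beta.shape[0]} probes x {beta.shape[1]} samples")

    beta2, ann2, truth_diff = synthetic.simulate_beta_matrix(
        n_genes=2000, n_probes=6200, probes_per_gene=3, n_differential_genes=40,
        delta_beta=0.35, n_differential_distal=30, noise_sd=0.05,
        group_split=(18, 123), n_xy_probes=0, n_snp_probes=0, seed=SEED,
    )
    gio.write_beta_csv(beta2, OUT / "beta_twogroup.csv")
    ann2.to_csv(OUT / "beta_twogroup.annotation.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": beta2.columns, "group": truth_diff["sample_groups"]}).to_csv(
        OUT / "beta_twogroup.groups.tsv", sep="\t", index=False
    )
    (OUT / "beta_twogroup.truth.json").write_text(
        json.dumps({
            "differential_genes": truth_diff["differential_genes"],
            "differential_distal_probes": truth_diff["differential_distal_probes"],
        })
    )
    print("two-group beta matrix: groups 18 vs 123, "
          "40 planted promoters, 30 planted distal probes")

    reads, truth_fus = synthetic.simulate_junction_reads(
        n_true_fusions=3, n_decoys=20, seed=SEED
    )
    pd.DataFrame([r.__dict__ for r in reads]).to_csv(
        OUT / "junction_reads.tsv", sep="\t", index=False
    )
    truth_fus.to_csv(OUT / "fusions.truth.tsv", sep="\t", index=False)
    print(f"junction reads: {len(reads)} reads, 3 true fusions, 20 decoys")

    records, truth_surv = synthetic.simulate_survival(hazard_ratio=4.0, seed=SEED)
    gio.write_survival_table(records, OUT / "survival.tsv")
    (OUT / "survival.truth.json").write_text(json.dumps(truth_surv))
    print(f"survival: {len(records)} subjects, hazard ratio 4")


if __name__ == "__main__":
    main()
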