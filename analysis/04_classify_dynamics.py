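#!/usr/bin/env python
"""Classify genes by in vivo growth dynamics and cluster response profiles.

Runs the in vivo GRO-vs-FGO contrast, labels genes LS/UP/DN/HS, tests which
groups are over-represented among affected genes (chi^2, Fig 5E/F-style),
and k-means-clusters the 5-effect response vectors of affected genes.
"""

from pathlib import Path

import pandas as pd

from stagefx import stage_model as sm
from stagefx.dynamics import classify_dynamics, kmeans_responses
from stagefx.enrichment import chisq_enrichment
from stagefx.io import read_counts, read_sample_table, write_tsv

SIM = Path("results/simulation")
OUT = Path("results/dynamics")
SEED = 17


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_counts(SIM / "counts.tsv")
    samples = read_sample_table(SIM / "samples.tsv")
    kept = [g.strip() for g in Path("results/quantify/kept_genes.txt").read_text().splitlines()]
    log_expr = pd.read_csv("results/quantify/logrpkm.tsv", sep="\t", index_col=0)
    calls = pd.read_csv("results/fit/affected_calls.tsv", sep="\t")

    invivo = [s for s in counts.sample_ids if "invivo" in s]
    groups = {s: ("GRO_invivo" if s.startswith("GRO") else "FGO_invivo") for s in invivo}
    de = sm.de_two_group(
        counts.subset_genes(kept).subset_samples(invivo), groups,
        reference="GRO_invivo",
    )
    gro_cols = [s for s in invivo if s.startswith("GRO")]
    fgo_cols = [s for s in invivo if s.startswith("FGO")]
    labels = classify_dynamics(
        de, log_expr[gro_cols].mean(axis=1), log_expr[fgo_cols].mean(axis=1)
    )
    write_tsv(labels.rename_axis("gene_id").reset_index(), OUT / "dynamics_labels.tsv")
    print("dynamics groups:", labels.value_counts().to_dict())

    affected = set(calls["gene_id"])
    chi = chisq_enrichment(labels, affected & set(labels.index), set(labels.index))
    write_tsv(chi, OUT / "group_enrichment.tsv")
    print("enrichment among affected genes (log2 obs/exp, * = chi^2 p <= 1%):")
    for _, r in chi.iterrows():
        star = "*" if r["significant"] else " "
        print(f"  {r['group']}: {r['enrichment_log2']:+.2f}{star} "
              f"(obs {r['observed']}, exp {r['expected']:.1f})")

    # response-profile clustering of affected genes
    fits = {s: pd.read_csv(f"results/fit/fit_{s}.tsv", sep="\t", index_col=0)
            for s in ("GRO", "FGO")}
    resp = pd.concat(
        [
            fits["GRO"][["beta_log2_IVP", "beta_log2_IVD"]]
            .rename(columns=lambda c: c.replace("beta_log2_", "") + "@GRO"),
            fits["FGO"][["beta_log2_IVP", "beta_log2_IVD", "beta_log2_IVG"]]
            .rename(columns=lambda c: c.replace("beta_log2_", "") + "@FGO"),
        ],
        axis=1,
    ).dropna()
    aff_resp = resp.loc[resp.index.intersection(sorted(affected))]
    clusters, centroids = kmeans_responses(aff_resp, k=5, seed=SEED)
    write_tsv(clusters.rename_axis("gene_id").reset_index(), OUT / "clusters.tsv")
    write_tsv(centroids, OUT / "centroids.tsv", index=True)
    print(f"k-means (k=5) on {len(aff_resp)} affected genes; "
          f"cluster sizes {clusters.value_counts().sort_index().to_dict()}")


if __name__ == "__main__":
    main()
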