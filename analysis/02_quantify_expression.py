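#!/usr/bin/env python
"""Normalise and filter expression; PCA of relative expression.

Reads results/simulation/, writes logRPKM, the kept-gene list and PCA
scores to results/quantify/, and reports how much expression variance the
leading components carry (in the study, GRO-vs-FGO stage dominated PC1).
"""

from pathlib import Path

from stagefx import quantify as q
from stagefx.io import read_counts, read_gene_models, read_sample_table, write_tsv
from stagefx.types import COHORT_STAGE

SIM = Path("results/simulation")
OUT = Path("results/quantify")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_counts(SIM / "counts.tsv")
    samples = read_sample_table(SIM / "samples.tsv")
    models = read_gene_models(SIM / "genes.bed")

    kept = q.filter_expressed(counts)  # CPM > 1 in >= 3 oocytes
    log_expr = q.log2_psc(q.rpkm(counts.subset_genes(kept), models), psc=0.1)
    partition = {
        s: COHORT_STAGE[c]
        for s, c in zip(samples.table["sample_id"], samples.table["cohort"])
    }
    rel = q.relative_expression(log_expr, partition)
    res = q.pca(rel)

    write_tsv(log_expr.to_frame(), OUT / "logrpkm.tsv", index=True)
    (OUT / "kept_genes.txt").write_text("\n".join(kept) + "\n")
    write_tsv(res.scores, OUT / "pca_scores.tsv", index=True)

    vf = res.variance_fraction
    print(f"kept {len(kept)}/{counts.n_genes} genes (CPM filter)")
    print(f"PC1 {vf[0]:.1%}, PC2 {vf[1]:.1%} of relative-expression variance")


if __name__ == "__main__":
    main()
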