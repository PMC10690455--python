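#!/usr/bin/env python
"""Generate the synthetic study: 7 single-oocyte cohorts with ground truth.

Writes counts, sample metadata, gene models, promoter sequences, chromatin
reads and the truth JSON under results/simulation/. Downstream analysis
scripts (02-08) consume these files only.
"""

from pathlib import Path

from stagefx import synthetic as syn
from stagefx.io import (
    write_counts,
    write_fasta,
    write_gene_models_bed12,
    write_read_intervals,
    write_tsv,
)

SEED = 17
OUT = Path("results/simulation")
# scale chosen for a desk-size walkthrough; the generator's full defaults
# (12,000 genes) are exercised by the acceptance suite
CONFIG = syn.SimulationConfig(n_genes=2000, cohort_size=23, affected_fraction=0.03)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = syn.make_truth(CONFIG, SEED)
    genome = syn.simulate_genome(truth, CONFIG)
    counts, samples = syn.simulate_counts(truth, CONFIG)

    truth.to_json(OUT / "truth.json")
    write_counts(counts, OUT / "counts.tsv")
    write_tsv(samples.table, OUT / "samples.tsv")
    write_gene_models_bed12(genome.models, OUT / "genes.bed")
    write_fasta(genome.promoter_sequences, OUT / "promoters.fa")
    for i, mark in enumerate(syn.REPRESSIVE_MARKS + syn.ACTIVE_MARKS):
        rs = syn.simulate_chip_reads(truth, genome, mark, seed=SEED + 100 + i)
        write_read_intervals(rs, OUT / f"reads_{mark}.bed")

    n_aff = int((truth.beta.abs() >= 2).any(axis=1).sum())
    print(f"simulated {CONFIG.n_genes} genes x {counts.n_samples} oocytes "
          f"(7 cohorts x {CONFIG.cohort_size})")
    print(f"planted affected genes: {n_aff}; "
          f"Polycomb targets: {int(truth.polycomb_target.sum())}")
    print(f"dynamics groups: {truth.dynamics.value_counts().to_dict()}")


if __name__ == "__main__":
    main()
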