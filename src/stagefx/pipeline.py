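"""End-to-end orchestration: simulate -> quantify -> fit -> classify ->
promoters -> enrich -> chromatin -> report, from one flat config.

Every stage writes plain TSV/JSON artifacts into the output directory and
can be re-run from the intermediates; the config (including every
statistical threshold and all seeds) is serialised alongside so deviations
from defaults are visible. Reruns under the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin as chrom_mod
from . import dynamics as dyn_mod
from . import enrichment as enr_mod
from . import promoters as prom_mod
from . import quantify as q_mod
from . import stage_model as sm
from . import synthetic as syn
from .io import write_counts, write_fasta, write_gene_models_bed12, write_tsv
from .types import COHORT_STAGE


@dataclass
class PipelineConfig:
    seed: int = 0
    # simulation scale (defaults follow SimulationConfig study scale)
    n_genes: int = 12000
    cohort_size: int = 23
    cgi_fraction: float = 0.5
    affected_fraction: float = 0.02
    chip_enrich_factor: float = 8.0
    chip_reads: int = 200_000
    # statistical thresholds, each the printed default of its analysis
    fdr_max: float = 0.05
    lfc_min: float = 2.0
    dynamics_lfc_min: float = 1.0
    dynamics_low_expr_max: float = 2.0
    chisq_p_max: float = 0.01
    mw_fdr_max: float = 0.001
    motif_fdr_max: float = 0.01
    go_p_max: float = 1e-4
    go_enrichment_min: float = 2.0
    psc: float = 0.1
    min_cpm: float = 1.0
    min_samples: int = 3
    kmeans_k: int = 5
    kmeans_restarts: int = 20
    display_lfc_min: float = 1.0

    def validate(self) -> None:
        for name in (
            "fdr_max", "chisq_p_max", "mw_fdr_max", "motif_fdr_max", "go_p_max",
        ):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.psc <= 0:
            raise ValueError("psc must be positive")
        if self.n_genes < 10 or self.cohort_size < 2:
            raise ValueError("n_genes >= 10 and cohort_size >= 2 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def simulation_config(self) -> syn.SimulationConfig:
        return syn.SimulationConfig(
            n_genes=self.n_genes,
            cohort_size=self.cohort_size,
            cgi_fraction=self.cgi_fraction,
            affected_fraction=self.affected_fraction,
        )


def zero_nonsignificant(fit: sm.StageEffectFit, fdr_max: float = 0.05) -> pd.DataFrame:
    """Display rule: responses with FDR >= fdr_max are set to 0."""
    tab = fit.table.copy()
    for eff in fit.effects:
        mask = tab[f"fdr_{eff}"] >= fdr_max
        tab.loc[mask, f"beta_log2_{eff}"] = 0.0
    return tab[[f"beta_log2_{e}" for e in fit.effects]]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on synthetic inputs; returns a summary dict."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}

    # --- simulate ---------------------------------------------------------
    sim_cfg = config.simulation_config()
    truth = syn.make_truth(sim_cfg, config.seed)
    genome = syn.simulate_genome(truth, sim_cfg)
    counts, samples = syn.simulate_counts(truth, sim_cfg)
    truth.to_json(out / "truth.json")
    write_counts(counts, out / "counts.tsv")
    write_tsv(samples.table, out / "samples.tsv")
    write_gene_models_bed12(genome.models, out / "genes.bed")
    write_fasta(genome.promoter_sequences, out / "promoters.fa")

    # --- quantify ---------------------------------------------------------
    kept = q_mod.filter_expressed(counts, config.min_cpm, config.min_samples)
    sub = counts.subset_genes(kept)
    log_expr = q_mod.log2_psc(q_mod.rpkm(sub, genome.models), config.psc)
    partition = {
        s: COHORT_STAGE[c]
        for s, c in zip(samples.table["sample_id"], samples.table["cohort"])
    }
    rel = q_mod.relative_expression(log_expr, partition)
    pca_res = q_mod.pca(rel)
    write_tsv(log_expr.to_frame(), out / "logrpkm.tsv", index=True)
    write_tsv(pca_res.scores, out / "pca_scores.tsv", index=True)
    summary["n_genes_kept"] = len(kept)
    summary["pca_variance_fraction"] = pca_res.variance_fraction[:5].tolist()

    # --- stage-effect fits ------------------------------------------------
    fits: dict[str, sm.StageEffectFit] = {}
    calls = []
    for stage in ("GRO", "FGO"):
        fit = sm.fit_stage_effects(counts, samples, stage, genes=kept)
        fits[stage] = fit
        write_tsv(fit.table, out / f"fit_{stage}.tsv", index=True)
        calls.append(sm.call_affected(fit, config.fdr_max, config.lfc_min))
    calls = pd.concat(calls, ignore_index=True)
    write_tsv(calls, out / "affected_calls.tsv")
    summary["affected_per_effect"] = (
        calls.groupby(["effect", "direction"]).size().to_dict()
    )
    summary["affected_per_effect"] = {
        f"{k[0]}_{k[1]}": int(v) for k, v in summary["affected_per_effect"].items()
    }
    affected_genes = set(calls["gene_id"])
    summary["n_affected_genes"] = len(affected_genes)

    # --- dynamics classification -----------------------------------------
    invivo = [
        s for s, c in partition.items()
        if samples.table.set_index("sample_id").loc[s, "cohort"]
        in ("GRO_invivo", "FGO_invivo")
    ]
    cm_iv = counts.subset_genes(kept).subset_samples(invivo)
    groups_iv = {
        s: samples.table.set_index("sample_id").loc[s, "cohort"] for s in invivo
    }
    de_iv = sm.de_two_group(
        cm_iv, groups_iv, config.fdr_max, config.dynamics_lfc_min,
        reference="GRO_invivo",
    )
    # positive beta_log2 = higher in FGO_invivo (GRO_invivo is the reference)
    lf = log_expr.to_frame()
    iv_gro = [s for s in invivo if groups_iv[s] == "GRO_invivo"]
    iv_fgo = [s for s in invivo if groups_iv[s] == "FGO_invivo"]
    labels = dyn_mod.classify_dynamics(
        de_iv, lf[iv_gro].mean(axis=1), lf[iv_fgo].mean(axis=1),
        config.fdr_max, config.dynamics_lfc_min, config.dynamics_low_expr_max,
    )
    write_tsv(labels.rename("group").reset_index().rename(columns={"index": "gene_id"}),
              out / "dynamics_labels.tsv")
    summary["group_sizes"] = labels.value_counts().to_dict()

    # --- response clustering (genes with all 5 effects defined) ----------
    resp = pd.concat(
        [
            fits["GRO"].table[["beta_log2_IVP", "beta_log2_IVD"]].rename(
                columns={"beta_log2_IVP": "IVP@GRO", "beta_log2_IVD": "IVD@GRO"}
            ),
            fits["FGO"].table[["beta_log2_IVP", "beta_log2_IVD", "beta_log2_IVG"]].rename(
                columns={
                    "beta_log2_IVP": "IVP@FGO",
                    "beta_log2_IVD": "IVD@FGO",
                    "beta_log2_IVG": "IVG@FGO",
                }
            ),
        ],
        axis=1,
    ).dropna()
    aff_resp = resp.loc[resp.index.intersection(sorted(affected_genes))]
    if len(aff_resp) >= config.kmeans_k:
        clusters, centroids = dyn_mod.kmeans_responses(
            aff_resp, config.kmeans_k, config.seed, config.kmeans_restarts
        )
        write_tsv(clusters.reset_index().rename(columns={"index": "gene_id"}),
                  out / "response_clusters.tsv")
        write_tsv(centroids, out / "cluster_centroids.tsv", index=True)
        summary["cluster_sizes"] = clusters.value_counts().sort_index().to_dict()

    # --- promoter features ------------------------------------------------
    proms, dropped = prom_mod.build_promoters(
        genome.models, genome.contig_lengths, seed=config.seed
    )
    proms, gmm = prom_mod.annotate_promoters(proms, genome.promoter_sequences, config.seed)
    prom_tab = pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in proms],
            "chrom": [p.chrom for p in proms],
            "start": [p.start for p in proms],
            "end": [p.end for p in proms],
            "cpg_obs_exp": [p.cpg_obs_exp for p in proms],
            "posterior_cgi": [p.posterior_cgi for p in proms],
            "cgi": [p.cgi for p in proms],
        }
    )
    write_tsv(prom_tab, out / "promoters.tsv")
    summary["n_promoters"] = len(proms)
    summary["n_promoters_dropped"] = len(dropped)
    summary["gmm_means"] = list(gmm.means)

    # CGI classification accuracy vs truth
    truth_cgi = truth.promoter_class.loc[prom_tab["gene_id"]] == "CGI"
    summary["cgi_accuracy"] = float(
        (prom_tab["cgi"].to_numpy() == truth_cgi.to_numpy()).mean()
    )

    # --- enrichment -------------------------------------------------------
    universe = set(labels.index)
    target = affected_genes & universe
    if target:
        chi = enr_mod.chisq_enrichment(labels, target, universe, config.chisq_p_max)
        write_tsv(chi, out / "group_enrichment.tsv")
        summary["group_enrichment"] = {
            r["group"]: round(float(r["enrichment_log2"]), 3) for _, r in chi.iterrows()
        }

    # --- chromatin marks --------------------------------------------------
    read_sets = [
        syn.simulate_chip_reads(
            truth, genome, mark, enrich_factor=config.chip_enrich_factor,
            n_reads=config.chip_reads, seed=config.seed + 100 + i,
        )
        for i, mark in enumerate(syn.REPRESSIVE_MARKS + syn.ACTIVE_MARKS)
    ]
    raw, logc, z = chrom_mod.promoter_mark_matrix(read_sets, proms)
    write_tsv(z, out / "promoter_mark_zscores.tsv", index=True)
    strata = pd.DataFrame(
        {
            "group": labels.reindex(prom_tab["gene_id"]).to_numpy(),
            "cgi": prom_tab["cgi"].to_numpy(),
        },
        index=prom_tab["gene_id"],
    ).dropna()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mw = chrom_mod.mw_affected_test(z, affected_genes, strata, config.mw_fdr_max)
    write_tsv(mw, out / "chromatin_tests.tsv")
    if len(mw):
        summary["n_significant_chromatin_strata"] = int(mw["significant"].sum())

    # --- display table (non-significant responses zeroed) -----------------
    for stage in ("GRO", "FGO"):
        write_tsv(
            zero_nonsignificant(fits[stage], config.fdr_max),
            out / f"display_responses_{stage}.tsv",
            index=True,
        )

    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, default=str, indent=1))
    return summary
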