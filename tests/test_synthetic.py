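import numpy as np
import pytest

from stagefx import synthetic as syn
from stagefx.promoters import cpg_obs_exp


class TestTruth:
    def test_group_and_class_fractions(self, small_truth, small_config):
        frac_cgi = (small_truth.promoter_class == "CGI").mean()
        assert frac_cgi == pytest.approx(small_config.cgi_fraction, abs=0.01)
        assert set(small_truth.dynamics.unique()) == {"LS", "UP", "DN", "HS"}

    def test_up_genes_have_planted_shift(self, small_truth):
        up = small_truth.dynamics == "UP"
        shift = small_truth.baseline_log2cpm_fgo - small_truth.baseline_log2cpm_gro
        assert np.all(shift[up.to_numpy()] >= 1.2)
        ls = (small_truth.dynamics == "LS").to_numpy()
        assert np.allclose(shift[ls], 0.0)

    def test_truth_roundtrip(self, small_truth, tmp_path):
        p = tmp_path / "truth.json"
        small_truth.to_json(p)
        t2 = syn.SimulationTruth.from_json(p)
        assert t2.gene_ids == small_truth.gene_ids
        assert np.allclose(t2.beta.to_numpy(), small_truth.beta.to_numpy())
        assert (t2.dynamics == small_truth.dynamics).all()

    def test_min_genes_validated(self):
        with pytest.raises(ValueError):
            syn.make_truth(syn.SimulationConfig(n_genes=5), 0)


class TestSimulateGenome:
    def test_cgi_fraction_zero(self):
        cfg = syn.SimulationConfig(n_genes=50, cgi_fraction=0.0)
        truth = syn.make_truth(cfg, 0)
        assert (truth.promoter_class == "nonCGI").all()

    def test_realized_cpg_ratio_tracks_target(self):
        cfg = syn.SimulationConfig(n_genes=500, cohort_size=2)
        truth = syn.make_truth(cfg, 9)
        genome = syn.simulate_genome(truth, cfg)
        ratios = np.array(
            [cpg_obs_exp(genome.promoter_sequences[g]) for g in truth.gene_ids]
        )
        cgi = (truth.promoter_class == "CGI").to_numpy()
        assert abs(ratios[cgi].mean() - 0.75) <= 0.05
        assert abs(ratios[~cgi].mean() - 0.25) <= 0.05

    def test_tss_strand_convention(self, small_genome):
        for m in small_genome.models[:50]:
            if m.strand == "+":
                assert m.tss == m.exons[0][0]
            else:
                assert m.tss == m.exons[-1][1] - 1


class TestSimulateCounts:
    def test_poisson_limit_mean_variance(self):
        # equal library sizes so across-sample variance is purely counting noise
        cfg = syn.SimulationConfig(
            n_genes=40, cohort_size=25, affected_fraction=1e-9,
            lib_size_range=(1e6, 1e6),
        )
        truth = syn.make_truth(cfg, 10)
        truth.beta.loc[:, :] = 0.0
        truth.dispersion[:] = 1e-13
        counts, samples = syn.simulate_counts(truth, cfg)
        iv = [s for s in counts.sample_ids if s.startswith("GRO_invivo")]
        sub = counts.subset_samples(iv)
        m = sub.counts.mean(axis=1)
        v = sub.counts.var(axis=1, ddof=1)
        big = m > 20
        assert np.median(v[big] / m[big]) == pytest.approx(1.0, abs=0.35)

    def test_planted_effect_shifts_cohort_mean(self):
        cfg = syn.SimulationConfig(n_genes=20, cohort_size=25)
        truth = syn.make_truth(cfg, 11)
        truth.beta.loc[:, :] = 0.0
        g = truth.gene_ids[0]
        truth.baseline_log2cpm_gro[0] = 6.0
        truth.dispersion[0] = 0.05
        truth.beta.loc[g, "IVD@GRO"] = 2.0
        counts, _ = syn.simulate_counts(truth, cfg)
        cpm = counts.counts / (counts.library_size / 1e6)
        pgc = [i for i, s in enumerate(counts.sample_ids) if s.startswith("GRO_PGC")]
        iv = [i for i, s in enumerate(counts.sample_ids) if s.startswith("GRO_invivo")]
        ratio = cpm[0, pgc].mean() / cpm[0, iv].mean()
        assert ratio == pytest.approx(4.0, rel=0.25)

    def test_same_seed_identical(self, small_truth, small_config):
        c1, _ = syn.simulate_counts(small_truth, small_config, seed=3)
        c2, _ = syn.simulate_counts(small_truth, small_config, seed=3)
        assert np.array_equal(c1.counts, c2.counts)

    def test_unknown_cohort_rejected(self, small_truth, small_config):
        with pytest.raises(ValueError):
            syn.simulate_counts(small_truth, small_config, cohort_sizes={"XXX": 3})


class TestSimulateChipReads:
    def test_uniform_when_factor_one(self, small_truth, small_genome, small_config):
        rs = syn.simulate_chip_reads(
            small_truth, small_genome, "H3K27me3", enrich_factor=1.0,
            n_reads=100_000, seed=1,
        )
        from scipy.stats import chisquare

        clen = small_genome.contig_lengths["chr1"]
        mids = rs.intervals.mean(axis=1)
        bins = np.histogram(mids, bins=20, range=(0, clen))[0]
        assert chisquare(bins).pvalue > 0.01

    def test_enrichment_magnitude(self, small_truth, small_genome):
        from stagefx.chromatin import count_promoter_reads, log2cpm16
        from stagefx.promoters import build_promoters

        rs = syn.simulate_chip_reads(
            small_truth, small_genome, "H3K27me3", enrich_factor=8.0,
            n_reads=300_000, seed=2,
        )
        proms, _ = build_promoters(small_genome.models, small_genome.contig_lengths, seed=0)
        cnt, _ = count_promoter_reads(rs, proms)
        lc = log2cpm16(cnt, rs.total_mapped)
        tg = small_truth.polycomb_target.reindex(cnt.index).fillna(False).astype(bool)
        assert lc[tg].mean() - lc[~tg].mean() == pytest.approx(3.0, abs=0.5)

    def test_zero_reads_empty_set(self, small_truth, small_genome):
        rs = syn.simulate_chip_reads(small_truth, small_genome, "H3K27me3", n_reads=0)
        assert len(rs) == 0


class TestOtherGenerators:
    def test_embed_motif_plants_consensus(self, small_genome):
        seqs = syn.embed_motif(
            small_genome.promoter_sequences, "TACGATGC",
            list(small_genome.promoter_sequences)[:20], seed=0,
        )
        assert all("TACGATGC" in seqs[g] for g in list(seqs)[:20])

    def test_simulate_outcomes_rates_near_truth(self):
        table, reps = syn.simulate_outcomes(
            {"A": {"t": 0.6}, "B": {"t": 0.2}},
            {"A": {"t": 900}, "B": {"t": 900}},
            seed=0,
        )
        from stagefx.competence import transition_rates

        rates = transition_rates(table).set_index("condition")["rate_percent"]
        assert rates["A"] == pytest.approx(60, abs=5)
        assert rates["B"] == pytest.approx(20, abs=5)
        assert len(reps) == 6
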