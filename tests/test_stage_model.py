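import numpy as np
import pandas as pd
import pytest

from stagefx import stage_model as sm
from stagefx import synthetic as syn
from stagefx.types import CountMatrix, SampleTable


def _samples(cohort_counts):
    rows = []
    from stagefx.types import COHORT_STAGE

    for cohort, n in cohort_counts.items():
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{cohort}_{i}",
                    "cohort": cohort,
                    "stage": COHORT_STAGE[cohort],
                    "diameter_um": 70.0,
                }
            )
    return SampleTable(pd.DataFrame(rows))


class TestBuildDesign:
    def test_gro_rows_match_exposure_table(self):
        st = _samples({"GRO_iPSC": 1, "GRO_PGC": 1, "GRO_invivo": 1})
        X = sm.build_design(st, "GRO")
        assert list(X.columns) == ["intercept", "IVP", "IVD"]
        assert X.loc["GRO_iPSC_0"].tolist() == [1, 1, 1]
        assert X.loc["GRO_PGC_0"].tolist() == [1, 0, 1]
        assert X.loc["GRO_invivo_0"].tolist() == [1, 0, 0]

    def test_fgo_rows_match_exposure_table(self):
        st = _samples({"FGO_iPSC": 1, "FGO_PGC": 1, "FGO_6dpp": 1, "FGO_invivo": 1})
        X = sm.build_design(st, "FGO")
        assert list(X.columns) == ["intercept", "IVP", "IVD", "IVG"]
        assert X.loc["FGO_iPSC_0"].tolist() == [1, 1, 1, 1]
        assert X.loc["FGO_PGC_0"].tolist() == [1, 0, 1, 1]
        assert X.loc["FGO_6dpp_0"].tolist() == [1, 0, 0, 1]
        assert X.loc["FGO_invivo_0"].tolist() == [1, 0, 0, 0]

    def test_stage_mismatch_raises(self):
        st = _samples({"GRO_iPSC": 1})
        with pytest.raises(ValueError):
            sm.build_design(st, "FGO")


class TestFitNbGlm:
    def test_intercept_only_recovers_log_mean(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(40, 60).astype(float)
        off = np.zeros(60)
        beta, _, conv = sm.fit_nb_glm(y, np.ones((60, 1)), off, 0.1)
        assert conv
        assert beta[0] == pytest.approx(np.log(y.mean()), abs=1e-6)

    def test_poisson_limit_matches_statsmodels(self):
        import statsmodels.api as smapi

        rng = np.random.default_rng(1)
        n = 40
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        off = np.log(rng.uniform(0.5e6, 2e6, n))
        mu = np.exp(2.0 + 0.7 * X[:, 1] + off - np.log(1e6))
        y = rng.poisson(mu).astype(float)
        beta, _, _ = sm.fit_nb_glm(y, X, off, 0.0)
        ref = smapi.GLM(y, X, family=smapi.families.Poisson(), offset=off).fit()
        assert np.allclose(beta, ref.params, atol=1e-6)

    def test_duplicated_column_raises_rank_error(self):
        y = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(np.linalg.LinAlgError):
            sm.fit_nb_glm(y, X, np.zeros(10), 0.1)


class TestDispersion:
    def test_poisson_data_gives_small_phi(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(30, (300, 100)).astype(float)
        phi, _ = sm.estimate_dispersion(y, np.ones((100, 1)), np.zeros(100))
        assert np.median(phi) <= 0.01

    def test_nb_phi_recovered(self):
        rng = np.random.default_rng(3)
        G, N, true_phi = 800, 150, 0.4
        lam = rng.gamma(1 / true_phi, true_phi * 50.0, (G, N))
        y = rng.poisson(lam).astype(float)
        phi, _ = sm.estimate_dispersion(y, np.ones((N, 1)), np.zeros(N))
        assert abs(np.median(phi) - true_phi) <= 0.05

    def test_constant_counts_hit_floor(self):
        y = np.full((12, 50), 7.0)
        phi, _ = sm.estimate_dispersion(y, np.ones((50, 1)), np.zeros(50))
        assert np.all(phi <= 1e-3)


class TestLrt:
    def test_zero_effect_column_gives_null_result(self):
        st = _samples({"GRO_PGC": 4, "GRO_invivo": 4})
        X = sm.build_design(st, "GRO")  # IVP column all zero
        y = np.random.default_rng(4).poisson(20, 8).astype(float)
        stat, p = sm.lrt_effect(y, X, "IVP", np.zeros(8), 0.1)
        assert stat == 0.0 and p == 1.0

    def test_intercept_not_testable(self):
        st = _samples({"GRO_PGC": 4, "GRO_invivo": 4})
        X = sm.build_design(st, "GRO")
        with pytest.raises(ValueError):
            sm.lrt_effect(np.ones(8), X, "intercept", np.zeros(8), 0.1)

    def test_planted_effect_detected(self):
        cfg = syn.SimulationConfig(n_genes=60, cohort_size=25, affected_fraction=1e-9)
        truth = syn.make_truth(cfg, 5)
        truth.beta.loc[:, :] = 0.0
        truth.beta.iloc[:10, truth.beta.columns.get_loc("IVD@GRO")] = 2.0
        truth.dispersion[:] = 0.3
        counts, samples = syn.simulate_counts(truth, cfg)
        fit = sm.fit_stage_effects(counts, samples, "GRO")
        calls = sm.call_affected(fit, 0.05, 2.0)
        planted = set(truth.beta.index[:10])
        hs = truth.dynamics.iloc[:10] != "LS"  # low-expressed genes lack power
        recovered = planted & set(calls["gene_id"])
        assert len(recovered) >= 0.5 * hs.sum()


class TestCallAffected:
    def test_hand_bh_and_thresholds(self):
        tab = pd.DataFrame(
            {
                "beta_log2_IVD": [3.0, -2.5, 2.2, 0.1],
                "lrt_IVD": [0.0] * 4,
                "p_IVD": [0.001, 0.02, 0.04, 0.8],
                "fdr_IVD": sm.benjamini_hochberg([0.001, 0.02, 0.04, 0.8]),
                "dispersion": [0.1] * 4,
                "converged": [True] * 4,
                "dispersion_flagged": [False] * 4,
            },
            index=["a", "b", "c", "d"],
        )
        fit = sm.StageEffectFit("GRO", ("IVD",), tab)
        calls = sm.call_affected(fit, fdr_max=0.05, lfc_min=2.0)
        assert set(calls["gene_id"]) == {"a", "b"}
        assert calls.set_index("gene_id").loc["b", "direction"] == "down"

    def test_lfc_threshold_excludes(self):
        tab = pd.DataFrame(
            {
                "beta_log2_IVD": [1.9],
                "lrt_IVD": [30.0],
                "p_IVD": [1e-8],
                "fdr_IVD": [1e-8],
                "dispersion": [0.1],
                "converged": [True],
                "dispersion_flagged": [False],
            },
            index=["a"],
        )
        fit = sm.StageEffectFit("GRO", ("IVD",), tab)
        assert len(sm.call_affected(fit, lfc_min=2.0)) == 0

    def test_empty_gene_set(self):
        tab = pd.DataFrame(
            columns=[
                "beta_log2_IVD", "lrt_IVD", "p_IVD", "fdr_IVD",
                "dispersion", "converged", "dispersion_flagged",
            ]
        )
        fit = sm.StageEffectFit("GRO", ("IVD",), tab)
        assert len(sm.call_affected(fit)) == 0


class TestDeTwoGroup:
    def _counts(self, rng, n_genes=80, n=8, shift_genes=0, shift=0.0, phi=0.2):
        mu = np.full((n_genes, n), 50.0)
        mu[:shift_genes, n // 2 :] *= 2.0**shift
        lam = rng.gamma(1 / phi, phi * mu)
        y = rng.poisson(lam).astype(np.int64)
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{j}" for j in range(n)]
        cm = CountMatrix(genes, samples, y, np.full(n, 1e6))
        groups = {f"s{j}": ("A" if j < n // 2 else "B") for j in range(n)}
        return cm, groups

    def test_label_swap_flips_sign(self):
        rng = np.random.default_rng(6)
        cm, groups = self._counts(rng, shift_genes=10, shift=2.0)
        phi = np.full(cm.n_genes, 0.2)
        de1 = sm.de_two_group(cm, groups, dispersion=phi, reference="A")
        de2 = sm.de_two_group(cm, groups, dispersion=phi, reference="B")
        assert np.allclose(de1["beta_log2"], -de2["beta_log2"], atol=1e-6)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(7)
        cm, groups = self._counts(rng, n_genes=400, n=12)
        de = sm.de_two_group(cm, groups)
        assert (de["p"] < 0.05).mean() <= 0.07

    def test_planted_recovery(self):
        rng = np.random.default_rng(8)
        cm, groups = self._counts(rng, n_genes=400, n=8, shift_genes=100, shift=3.0)
        de = sm.de_two_group(cm, groups, reference="A")
        hits = de.iloc[:100]["significant"]
        assert hits.sum() >= 80
        assert (de.iloc[:100]["beta_log2"] > 0).mean() > 0.9

    def test_one_group_too_small(self):
        rng = np.random.default_rng(9)
        cm, groups = self._counts(rng, n=4)
        groups = {s: ("A" if i < 1 else "B") for i, s in enumerate(cm.sample_ids)}
        with pytest.raises(ValueError):
            sm.de_two_group(cm, groups)


class TestAdditivity:
    def test_ipsc_effect_sum_matches_direct_contrast(self, small_truth, small_config, small_dataset):
        """Fitted IVP@GRO + IVD@GRO should approximate the direct
        GRO_iPSC - GRO_invivo log2 contrast (the additive design is exact)."""
        counts, samples = small_dataset
        from stagefx.quantify import filter_expressed

        kept = filter_expressed(counts)
        fit = sm.fit_stage_effects(counts, samples, "GRO", genes=kept)
        tab = fit.table[fit.table["converged"]]
        summed = tab["beta_log2_IVP"] + tab["beta_log2_IVD"]

        cpm = counts.subset_genes(list(tab.index))
        vals = cpm.counts / (cpm.library_size / 1e6)
        sel = lambda coh: [i for i, s in enumerate(cpm.sample_ids) if s.startswith(coh)]
        m_ipsc = vals[:, sel("GRO_iPSC")].mean(axis=1)
        m_iv = vals[:, sel("GRO_invivo")].mean(axis=1)
        ok = (m_ipsc > 20) & (m_iv > 20)
        direct = np.log2(m_ipsc[ok] / m_iv[ok])
        assert np.abs(summed[ok] - direct).mean() < 0.3
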