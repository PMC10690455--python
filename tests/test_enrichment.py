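import itertools

import numpy as np
import pandas as pd
import pytest

from stagefx import enrichment as enr
from stagefx.types import PWM


class TestChisqEnrichment:
    def test_worked_example(self):
        universe = {f"g{i}" for i in range(10_000)}
        up = {f"g{i}" for i in range(2_000)}
        membership = pd.Series(
            {g: ("UP" if g in up else "other") for g in universe}
        )
        target = {f"g{i}" for i in range(150)} | {f"g{i}" for i in range(2000, 2150)}
        res = enr.chisq_enrichment(membership, target, universe).set_index("group")
        assert res.loc["UP", "observed"] == 150
        assert res.loc["UP", "expected"] == pytest.approx(60.0)
        assert res.loc["UP", "enrichment_log2"] == pytest.approx(np.log2(151 / 61), abs=1e-9)

    def test_balanced_table_null(self):
        universe = {f"g{i}" for i in range(100)}
        membership = pd.Series({g: ("A" if int(g[1:]) % 2 else "B") for g in universe})
        target = {f"g{i}" for i in range(0, 100, 4)} | {f"g{i}" for i in range(1, 100, 4)}
        res = enr.chisq_enrichment(membership, target, universe)
        assert np.allclose(res["enrichment_log2"], 0.0, atol=1e-12)
        assert np.allclose(res["p"], 1.0)

    def test_statistic_matches_hand_formula(self):
        table = np.array([[10, 10], [10, 10]])
        assert enr.chisq_stat_2x2(table) == pytest.approx(0.0)
        table = np.array([[30, 10], [15, 45]])
        from scipy.stats import chi2_contingency

        stat, _, _, _ = chi2_contingency(table, correction=False)
        assert enr.chisq_stat_2x2(table) == pytest.approx(stat)

    def test_expected_sums_to_target_size(self):
        universe = {f"g{i}" for i in range(300)}
        membership = pd.Series({g: f"grp{int(g[1:]) % 3}" for g in universe})
        target = {f"g{i}" for i in range(50)}
        res = enr.chisq_enrichment(membership, target, universe)
        assert res["expected"].sum() == pytest.approx(50.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            enr.chisq_enrichment(pd.Series(dtype=object), set(), set())


class TestFisherGo:
    def test_exact_tail_probability(self):
        # universe 20, term covers 5, study 5, overlap 4:
        # p = [C(5,4)C(15,1) + C(5,5)C(15,0)] / C(20,5) = 76/15504
        universe = {f"g{i}" for i in range(20)}
        ann = {f"g{i}": {"T"} for i in range(5)}
        study = {"g0", "g1", "g2", "g3", "g10"}
        res = enr.fisher_go(study, universe, ann, min_annotated=1)
        assert res.table.iloc[0]["p"] == pytest.approx(76 / 15504, rel=1e-12)

    def test_expected_overlap_gives_enrichment_one(self):
        universe = {f"g{i}" for i in range(100)}
        ann = {f"g{i}": {"T"} for i in range(50)}
        study = {f"g{i}" for i in range(0, 100, 10)}  # 10 genes, 5 annotated
        res = enr.fisher_go(study, universe, ann, min_annotated=1)
        assert res.table.iloc[0]["enrichment"] == pytest.approx(1.0)

    def test_study_equals_universe_degenerate(self):
        universe = {f"g{i}" for i in range(30)}
        ann = {f"g{i}": {"T"} for i in range(10)}
        res = enr.fisher_go(universe, universe, ann, min_annotated=1)
        assert res.table.iloc[0]["p"] == pytest.approx(1.0)
        assert res.table.iloc[0]["enrichment"] == pytest.approx(1.0)

    def test_elim_removes_genes_from_ancestors(self):
        universe = {f"g{i}" for i in range(40)}
        child_genes = {f"g{i}" for i in range(10)}
        ann = {}
        for g in universe:
            terms = set()
            if g in child_genes:
                terms |= {"child", "parent"}
            if int(g[1:]) < 20:
                terms.add("parent")
            if terms:
                ann[g] = terms
        study = set(list(child_genes)[:8])
        plain = enr.fisher_go(study, universe, ann, min_annotated=3)
        elim = enr.fisher_go(
            study, universe, ann, min_annotated=3,
            dag_parents={"child": {"parent"}}, elim_p=0.05,
        )
        p_parent_plain = plain.table.set_index("term").loc["parent", "p"]
        p_parent_elim = elim.table.set_index("term").loc["parent", "p"]
        assert p_parent_elim > p_parent_plain


class TestJaccardMds:
    def test_known_distance(self):
        sets = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"}}
        _, D = enr.jaccard_mds(sets)
        assert D.loc["A", "B"] == pytest.approx(0.5)

    def test_identical_sets_distance_zero(self):
        sets = {"A": {"a"}, "B": {"a"}, "C": {"a", "b"}}
        _, D = enr.jaccard_mds(sets)
        assert D.loc["A", "B"] == 0.0

    def test_planar_configuration_recovered(self):
        # three sets whose Jaccard distances are exactly embeddable
        sets = {
            "A": {1, 2, 3, 4},
            "B": {3, 4, 5, 6},
            "C": {1, 2, 5, 6},
        }
        coords, D = enr.jaccard_mds(sets)
        for t1, t2 in itertools.combinations(sets, 2):
            d_emb = np.linalg.norm(coords.loc[t1] - coords.loc[t2])
            assert d_emb == pytest.approx(D.loc[t1, t2], abs=1e-8)

    def test_triangle_inequality_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sets = {
                k: set(rng.choice(30, size=rng.integers(1, 15), replace=False))
                for k in "ABC"
            }
            _, D = enr.jaccard_mds(sets)
            for a, b, c in itertools.permutations("ABC"):
                assert D.loc[a, c] <= D.loc[a, b] + D.loc[b, c] + 1e-12


class TestScanPwm:
    def _degenerate(self, word="TACGAT"):
        idx = {b: i for i, b in enumerate("ACGT")}
        mat = np.zeros((4, len(word)))
        for j, b in enumerate(word):
            mat[idx[b], j] = 100.0
        return PWM("W", mat)

    def test_degenerate_pwm_hits_word_and_revcomp(self):
        pwm = self._degenerate("TACGAT")
        seqs = {
            "has_fwd": "AAAAATACGATAAAAA",
            "has_rev": "AAAAATCGTAAAAAA" + "A",  # revcomp(TACGAT)=ATCGTA
            "none": "AAAAACCCCCGGGGG" + "A",
        }
        seqs["has_rev"] = "AAAA" + "ATCGTA" + "AAAA"
        res = enr.scan_pwm(pwm, seqs, score_quantile=0.999).set_index("seq_id")
        assert bool(res.loc["has_fwd", "hit"])
        assert bool(res.loc["has_rev", "hit"])
        assert not bool(res.loc["none", "hit"])

    def test_sequence_shorter_than_motif(self):
        pwm = self._degenerate("TACGATGG")
        res = enr.scan_pwm(pwm, {"short": "ACG"})
        assert res.iloc[0]["n_hits"] == 0

    def test_quantile_one_keeps_only_max_score(self):
        pwm = self._degenerate("ACG")
        thr = enr.score_threshold(pwm, np.full(4, 0.25), quantile=1.0)
        lom = enr.pwm_log_odds(pwm, np.full(4, 0.25))
        # threshold lives on the 1e-3-discretised DP grid
        assert thr == pytest.approx(lom.max(axis=0).sum(), abs=3e-3)

    @pytest.mark.parametrize("word", ["TACG", "GGCCA", "ATATAT"])
    def test_dp_distribution_matches_enumeration(self, word):
        pwm = self._degenerate(word)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        lom = enr.pwm_log_odds(pwm, bg)
        precision = 1e-4
        scores, probs = enr.score_distribution(lom, bg, precision=precision)
        # brute force over all 4^L words on the same discretised grid
        idx = {b: i for i, b in enumerate("ACGT")}
        q = np.round(lom / precision).astype(np.int64)
        brute: dict[int, float] = {}
        for letters in itertools.product("ACGT", repeat=len(word)):
            s = sum(q[idx[c], j] for j, c in enumerate(letters))
            p = np.prod([bg[idx[c]] for c in letters])
            brute[s] = brute.get(s, 0.0) + p
        assert probs.sum() == pytest.approx(1.0)
        assert len(scores) == len(brute)
        for s_dp, p_dp in zip(scores, probs):
            key = int(round(s_dp / precision))
            assert p_dp == pytest.approx(brute[key], rel=1e-9, abs=1e-15)


class TestBinnedMotifEnrichment:
    def _hits(self, rng, rates, n_per_bin):
        rows = []
        for b, (rate, n) in enumerate(zip(rates, n_per_bin)):
            for i in range(n):
                rows.append(
                    {
                        "gene_id": f"b{b}_g{i}",
                        "motif_id": "M",
                        "hit": bool(rng.random() < rate),
                    }
                )
        hits = pd.DataFrame(rows)
        bins = pd.Series(
            {r["gene_id"]: f"bin{r['gene_id'].split('_')[0][1:]}" for _, r in hits.iterrows()}
        )
        return bins, hits

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(0)
        bins, hits = self._hits(rng, [0.5, 0.05, 0.05], [100, 450, 450])
        res = enr.binned_motif_enrichment(bins, hits)
        row = res[(res["bin"] == "bin0")].iloc[0]
        assert row["significant"]

    def test_uniform_rates_mostly_null(self):
        sig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            bins, hits = self._hits(rng, [0.2, 0.2, 0.2], [100, 100, 100])
            res = enr.binned_motif_enrichment(bins, hits)
            sig += int(res["significant"].any())
        assert sig <= 1  # >= 95% of replicates with no calls

    def test_fisher_p_equals_hypergeometric_tail(self):
        from scipy.stats import fisher_exact

        bins = pd.Series({**{f"a{i}": "A" for i in range(5)}, **{f"b{i}": "B" for i in range(15)}})
        hit_genes = {"a0", "a1", "a2", "a3", "b0"}
        hits = pd.DataFrame(
            {
                "gene_id": list(bins.index),
                "motif_id": "M",
                "hit": [g in hit_genes for g in bins.index],
            }
        )
        res = enr.binned_motif_enrichment(bins, hits).set_index("bin")
        table = [[4, 1], [1, 14]]
        _, p_ref = fisher_exact(table, alternative="greater")
        assert res.loc["A", "p"] == pytest.approx(p_ref, rel=1e-10)
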