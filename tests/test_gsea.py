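"""Pre-ranked GSEA: exact running-sum scores, permutation null, calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest

from grexmeta.gsea import (enrichment_score, preranked_gsea, rank_genes,
                           read_gmt)


def _ranked(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(len(scores))]
    return pd.DataFrame({"gene_id": genes, "score": scores})


class TestEnrichmentScore:
    def test_hand_enumerated_example(self):
        ranked = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, running, leading = enrichment_score(ranked, {"g0", "g2"}, 1.0)
        np.testing.assert_allclose(
            running, [0.625, 0.2917, 0.6667, 0.3333, 0.0], atol=1e-4)
        assert es == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert leading == ["g0", "g2"]

    def test_single_top_gene(self):
        ranked = _ranked([5.0, 4.0, 3.0])
        es, _, leading = enrichment_score(ranked, {"g0"}, 1.0)
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_full_list_rejected(self):
        ranked = _ranked([3.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            enrichment_score(ranked, {"g0", "g1", "g2"}, 1.0)

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(_ranked([1.0, 2.0]), {"zz"}, 1.0)

    def test_monotone_rescaling_invariance_exponent_zero(self):
        rng = np.random.default_rng(0)
        scores = np.sort(rng.uniform(0.1, 10, 12))[::-1]
        genes = [f"g{i}" for i in range(12)]
        s = {"g2", "g5", "g9"}
        es1, _, _ = enrichment_score(_ranked(scores, genes), s, 0.0)
        es2, _, _ = enrichment_score(_ranked(np.log(scores) + 5, genes), s, 0.0)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_reversal_negates_es_exponent_zero(self):
        rng = np.random.default_rng(1)
        n = 9
        genes = [f"g{i}" for i in range(n)]
        scores = np.sort(rng.uniform(1, 5, n))[::-1]
        s = {"g1", "g4"}
        es_f, run_f, _ = enrichment_score(_ranked(scores, genes), s, 0.0)
        es_r, run_r, _ = enrichment_score(
            _ranked(scores, genes[::-1]), s, 0.0)
        # reversing the list mirrors the running sum: deviations negate
        expected = np.append(-run_f[::-1][1:], 0.0)
        np.testing.assert_allclose(run_r, expected, atol=1e-12)
        assert es_r == pytest.approx(-es_f, abs=1e-12) or \
            abs(abs(es_r) - abs(es_f)) < 1e-12

    def test_matches_exhaustive_enumeration_small_n(self):
        """ES of every 2-subset of a 10-gene list, against a direct
        re-implementation of the running sum by explicit loop."""
        rng = np.random.default_rng(2)
        scores = np.sort(rng.uniform(0.5, 8, 10))[::-1]
        genes = [f"g{i}" for i in range(10)]
        ranked = _ranked(scores, genes)
        for subset in itertools.combinations(range(10), 2):
            s = {genes[i] for i in subset}
            es, _, _ = enrichment_score(ranked, s, 1.0)
            # oracle: explicit loop
            hit_total = sum(scores[i] for i in subset)
            running, cur, best = [], 0.0, 0.0
            for i in range(10):
                if i in subset:
                    cur += scores[i] / hit_total
                else:
                    cur -= 1.0 / 8
                running.append(cur)
                if abs(cur) > abs(best):
                    best = cur
            assert es == pytest.approx(best, abs=1e-12)


class TestPermutation:
    def test_permutation_p_matches_exact_enumeration(self):
        """For 2-subsets of a 10-gene list the permutation p must sit within
        3 Monte-Carlo SDs of the exact p from all C(10,2)=45 subsets."""
        rng = np.random.default_rng(3)
        scores = np.sort(rng.uniform(0.5, 8, 10))[::-1]
        genes = [f"g{i}" for i in range(10)]
        ranked = _ranked(scores, genes)
        target = {"g0", "g3"}
        es_obs, _, _ = enrichment_score(ranked, target, 1.0)
        null = []
        for subset in itertools.combinations(genes, 2):
            e, _, _ = enrichment_score(ranked, set(subset), 1.0)
            null.append(e)
        null = np.array(null)
        same = null[np.sign(null) == np.sign(es_obs)]
        # exact analogue of the permutation estimator: same-sign exceedances
        # over the total number of subsets
        p_exact = np.sum(np.abs(same) >= abs(es_obs)) / len(null)
        n_perm = 2000
        res = preranked_gsea(ranked, {"s": list(target)}, n_perm=n_perm,
                             seed=5, min_size=2)
        p_perm = res.loc[0, "p"]
        mc_sd = np.sqrt(p_exact * (1 - p_exact) / n_perm) + 1e-9
        assert abs(p_perm - p_exact) <= 3 * mc_sd + 2.0 / n_perm

    def test_null_sets_calibrated(self):
        rng = np.random.default_rng(6)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        ranked = _ranked(np.sort(rng.uniform(0, 5, n))[::-1], genes)
        sets = {f"s{i}": list(rng.choice(genes, 10, replace=False))
                for i in range(300)}
        res = preranked_gsea(ranked, sets, n_perm=400, seed=7)
        rej = float((res["p"] < 0.05).mean())
        assert 0.02 <= rej <= 0.08

    def test_planted_set_detected(self):
        rng = np.random.default_rng(8)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        ranked = _ranked(np.sort(rng.uniform(0, 5, n))[::-1], genes)
        planted = list(rng.choice(genes[: n // 10], 12, replace=False))
        sets = {"planted": planted}
        sets.update({f"r{i}": list(rng.choice(genes, 12, replace=False))
                     for i in range(20)})
        res = preranked_gsea(ranked, sets, n_perm=2000, seed=9)
        assert res.set_index("set").loc["planted", "padj"] < 0.05

    def test_p_floor(self):
        rng = np.random.default_rng(10)
        genes = [f"g{i}" for i in range(50)]
        ranked = _ranked(np.sort(rng.uniform(0, 5, 50))[::-1], genes)
        res = preranked_gsea(ranked, {"top": genes[:5]}, n_perm=200, seed=11)
        assert res.loc[0, "p"] >= 1.0 / 201.0

    def test_cross_check_against_reference_implementation(self):
        """ES agrees with the independently developed gseapy prerank tool."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(12)
        n = 60
        genes = [f"G{i}" for i in range(n)]
        scores = np.sort(rng.uniform(0.01, 6, n))[::-1]
        ranked = _ranked(scores, genes)
        members = list(rng.choice(genes, 8, replace=False))
        es_ours, _, _ = enrichment_score(ranked, members, 1.0)
        rnk = pd.Series(scores, index=genes)
        res = gseapy.prerank(rnk=rnk, gene_sets={"s": members},
                             permutation_num=10, min_size=2, max_size=50,
                             weight=1.0, seed=1, outdir=None,
                             no_plot=True).res2d
        es_ref = float(res["ES"].iloc[0])
        assert es_ours == pytest.approx(es_ref, abs=5e-3)


class TestRanking:
    def test_max_p_rule(self):
        meta = pd.DataFrame({
            "gene_id": ["g1"], "hmp_predixcan": [0.001],
            "ebm_predixcan": [0.01], "hmp_twas": [np.nan],
            "omnibus_twas": [np.nan]})
        ranked = rank_genes(meta, "predixcan")
        assert ranked.loc[0, "score"] == pytest.approx(2.0)

    def test_lexicographic_tiebreak(self):
        meta = pd.DataFrame({
            "gene_id": ["zzz", "aaa", "mmm"],
            "hmp_predixcan": [0.01] * 3, "ebm_predixcan": [0.01] * 3,
            "hmp_twas": [np.nan] * 3, "omnibus_twas": [np.nan] * 3})
        ranked = rank_genes(meta, "predixcan")
        assert list(ranked["gene_id"]) == ["aaa", "mmm", "zzz"]

    def test_unknown_platform_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(pd.DataFrame({"gene_id": []}), "other")


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\turl\tg9\n")
    sets = read_gmt(path)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}
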