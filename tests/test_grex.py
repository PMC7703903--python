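"""Allele harmonization, GReX imputation and cross-imputation comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grexmeta.grex import (GReXMatrix, HarmonizationError, compare_imputations,
                           harmonize_alleles, impute_grex)
from grexmeta.predictdb import ExpressionModel, ModelStore, WeightEntry
from grexmeta.simcohort import DosageMatrix, VariantRecord


def _model(entries, gene="G", tissue="t"):
    ws = [WeightEntry(vid, "chr1", pos, ea, oa, w, maf)
          for vid, pos, ea, oa, w, maf in entries]
    return ExpressionModel(gene, tissue, ws, 0.5, 0.001, 100, 1_000_000)


def _cohort(variant_specs, dosages):
    variants = [VariantRecord(vid, "chr1", pos, ref, alt, 0.2)
                for vid, pos, ref, alt in variant_specs]
    n = np.asarray(dosages, float).shape[0]
    return DosageMatrix([f"s{i}" for i in range(n)], variants,
                        np.asarray(dosages, float))


class TestHarmonize:
    # every (model ea/oa, cohort ref/alt) configuration over two distinct
    # non-complementary alleles plus the ambiguous pairs, with hand-written
    # expected outcomes
    TRUTH = [
        # ea, oa, ref, alt -> action (keep sign / flip / drop)
        ("A", "G", "G", "A", "keep"),
        ("G", "A", "G", "A", "flip"),
        ("A", "G", "A", "G", "flip"),
        ("G", "A", "A", "G", "keep"),
        ("A", "C", "C", "A", "keep"),
        ("C", "A", "C", "A", "flip"),
        ("A", "T", "T", "A", "ambiguous"),
        ("T", "A", "T", "A", "ambiguous"),
        ("C", "G", "G", "C", "ambiguous"),
        ("G", "C", "G", "C", "ambiguous"),
        ("A", "G", "T", "C", "mismatch"),
        ("A", "C", "G", "T", "mismatch"),
    ]

    @pytest.mark.parametrize("ea,oa,ref,alt,action", TRUTH)
    def test_allele_configurations(self, ea, oa, ref, alt, action):
        model = _model([("v0", 100, ea, oa, 0.5, None),
                        ("anchor", 200, "A", "G", 0.1, None)])
        cohort = _cohort([("v0", 100, ref, alt), ("anchor", 200, "G", "A")],
                         np.zeros((5, 2)))
        idx, w, offset, rep = harmonize_alleles(model, cohort.variants)
        if action == "keep":
            assert 0 in idx and w[idx.index(0)] == 0.5
        elif action == "flip":
            assert 0 in idx and w[idx.index(0)] == -0.5
            assert offset == pytest.approx(2 * 0.5)
        elif action == "ambiguous":
            assert rep.ambiguous_dropped == 1 and 0 not in idx
        else:
            assert rep.missing == 1 and 0 not in idx

    def test_unmatched_with_maf_mean_imputed(self):
        model = _model([("vX", 999, "A", "G", 0.5, 0.3),
                        ("anchor", 200, "A", "G", 0.1, None)])
        cohort = _cohort([("anchor", 200, "G", "A")], np.zeros((5, 1)))
        idx, w, offset, rep = harmonize_alleles(model, cohort.variants)
        assert rep.mean_imputed == 1
        assert offset == pytest.approx(0.5 * 2 * 0.3)

    def test_zero_matches_raises_distinctly(self):
        model = _model([("vX", 999, "A", "G", 0.5, None)])
        cohort = _cohort([("other", 1, "G", "A")], np.zeros((3, 1)))
        with pytest.raises(HarmonizationError):
            harmonize_alleles(model, cohort.variants)

    def test_match_by_position_and_alleles(self):
        model = _model([("rsDIFFERENT", 100, "A", "G", 0.5, None)])
        cohort = _cohort([("v0", 100, "G", "A")], np.zeros((3, 1)))
        idx, w, _, rep = harmonize_alleles(model, cohort.variants)
        assert idx == [0] and rep.matched == 1


class TestImpute:
    def test_single_variant(self):
        store = ModelStore()
        store.add(_model([("v0", 100, "A", "G", 0.5, None)]))
        cohort = _cohort([("v0", 100, "G", "A")], [[2.0], [0.0]])
        g = impute_grex(cohort, store)
        assert g.column("G", "t")[0] == pytest.approx(1.0)
        assert g.column("G", "t")[1] == pytest.approx(0.0)

    def test_cancellation(self):
        store = ModelStore()
        store.add(_model([("v0", 100, "A", "G", 1.0, None),
                          ("v1", 200, "C", "A", -1.0, None)]))
        cohort = _cohort([("v0", 100, "G", "A"), ("v1", 200, "A", "C")],
                         [[1.0, 1.0]])
        assert impute_grex(cohort, store).column("G", "t")[0] == pytest.approx(0.0)

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(5)
        entries = [(f"v{j}", 100 + j, "A", "G", float(w[j]), None)
                   for j in range(5)]
        store = ModelStore()
        store.add(_model(entries))
        D = rng.integers(0, 3, size=(10, 5)).astype(float)
        cohort = _cohort([(f"v{j}", 100 + j, "G", "A") for j in range(5)], D)
        got = impute_grex(cohort, store).column("G", "t")
        expected = np.array([sum(w[j] * D[i, j] for j in range(5))
                             for i in range(10)])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_empty_model_gives_zero_column(self):
        store = ModelStore()
        store.add(ExpressionModel("G", "t", [], 0.0, 1.0, 100, 1))
        cohort = _cohort([("v0", 100, "G", "A")], [[1.0], [2.0]])
        assert np.all(impute_grex(cohort, store).column("G", "t") == 0.0)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(0, 1))
    def test_linearity_in_dosages(self, alpha):
        rng = np.random.default_rng(1)
        entries = [(f"v{j}", 100 + j, "A", "G", float(rng.standard_normal()),
                    None) for j in range(4)]
        store = ModelStore()
        store.add(_model(entries))
        specs = [(f"v{j}", 100 + j, "G", "A") for j in range(4)]
        X1 = rng.uniform(0, 2, (6, 4))
        X2 = rng.uniform(0, 2, (6, 4))
        t1 = impute_grex(_cohort(specs, X1), store).column("G", "t")
        t2 = impute_grex(_cohort(specs, X2), store).column("G", "t")
        tmix = impute_grex(_cohort(specs, alpha * X1 + (1 - alpha) * X2),
                           store).column("G", "t")
        np.testing.assert_allclose(tmix, alpha * t1 + (1 - alpha) * t2,
                                   atol=1e-9)

    def test_flip_involution_identical_grex(self):
        """Relabelling cohort ref/alt (and complementing dosages) leaves
        GReX exactly unchanged."""
        rng = np.random.default_rng(2)
        entries = [(f"v{j}", 100 + j, "A", "G", float(rng.standard_normal()),
                    None) for j in range(4)]
        store = ModelStore()
        store.add(_model(entries))
        X = rng.integers(0, 3, (8, 4)).astype(float)
        straight = _cohort([(f"v{j}", 100 + j, "G", "A") for j in range(4)], X)
        flipped = _cohort([(f"v{j}", 100 + j, "A", "G") for j in range(4)],
                          2.0 - X)
        a = impute_grex(straight, store).column("G", "t")
        b = impute_grex(flipped, store).column("G", "t")
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCompare:
    def test_identical_columns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.standard_normal((50, 5)),
                          index=[f"s{i}" for i in range(50)],
                          columns=list("abcde"))
        res = compare_imputations(df, df.copy())
        assert res["mean_r2"] == pytest.approx(1.0)
        np.testing.assert_allclose(res["table"]["r"], 1.0, atol=1e-12)

    def test_independent_columns_match_null(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(1000)]
        cols = [f"g{i}" for i in range(200)]
        a = pd.DataFrame(rng.standard_normal((1000, 200)), index=idx,
                         columns=cols)
        b = pd.DataFrame(rng.standard_normal((1000, 200)), index=idx,
                         columns=cols)
        res = compare_imputations(a, b)
        assert res["mean_r2"] <= 0.005
        assert 0.01 <= res["null_exceedance"] <= 0.10

    def test_zero_variance_column_skipped(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(20)]
        a = pd.DataFrame({"g1": rng.standard_normal(20),
                          "g2": np.ones(20)}, index=idx)
        b = pd.DataFrame(rng.standard_normal((20, 2)), index=idx,
                         columns=["g1", "g2"])
        res = compare_imputations(a, b)
        assert res["skipped_zero_variance"] == 1
        assert len(res["table"]) == 1
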