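"""Tissue composition, signatures, origin prediction, gating, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from chromtrace.io import FeatureMatrix
from chromtrace.metacells import ArchetypeModel, assign_metacells
from chromtrace.similarity import AccessibleSet, ModulePartition
from chromtrace.tracing import (build_tissue_signatures, combinatorial_gate,
                                celltype_metacell_correlation, holdout_split,
                                marker_correlation, predict_origin,
                                prediction_accuracy, tissue_composition)


def _assignment(metacells, counts=None, n_ids=None):
    barcodes = [f"b{i}" for i in range(len(metacells))]
    n_ids = n_ids or max(metacells)
    if counts is None:
        counts = np.ones((len(metacells), 4))
    A = np.zeros((n_ids, len(metacells)))
    A[np.array(metacells) - 1, np.arange(len(metacells))] = 1.0
    model = ArchetypeModel(A=A, B=np.full((len(metacells), n_ids),
                                          1 / len(metacells)))
    m = FeatureMatrix(sp.csr_matrix(np.asarray(counts, float)), barcodes,
                     [f"p{j}" for j in range(np.asarray(counts).shape[1])],
                     "peak")
    return assign_metacells(model, m), m


class TestTissueComposition:
    def test_fractions_and_majority(self):
        asn, _ = _assignment([1] * 10)
        tissues = pd.Series(["liver"] * 7 + ["lung"] * 3,
                            index=[f"b{i}" for i in range(10)])
        comp = tissue_composition(asn, tissues)
        assert comp.loc[1, "liver"] == pytest.approx(0.7)
        assert comp.loc[1, "lung"] == pytest.approx(0.3)
        assert comp.loc[1, "majority_tissue"] == "liver"

    def test_rows_sum_to_one_and_conservation(self):
        rng = np.random.default_rng(0)
        ids = rng.integers(1, 6, size=60)
        asn, _ = _assignment(list(ids), n_ids=5)
        tissues = pd.Series(rng.choice(["a", "b", "c"], 60),
                            index=[f"b{i}" for i in range(60)])
        comp = tissue_composition(asn, tissues)
        nonempty = comp["size"] > 0
        np.testing.assert_allclose(
            comp.loc[nonempty, ["a", "b", "c"]].sum(axis=1), 1.0)
        for t in "abc":
            total = (comp[t] * comp["size"]).sum()
            assert total == pytest.approx((tissues == t).sum())

    def test_single_tissue_metacell_pure(self):
        asn, _ = _assignment([1, 1, 2])
        tissues = pd.Series(["x", "x", "y"], index=["b0", "b1", "b2"])
        comp = tissue_composition(asn, tissues)
        assert comp.loc[1, "purity"] == 1.0


class TestCelltypeCorrelation:
    def test_pure_metacell_correlates_with_its_type(self):
        rng = np.random.default_rng(1)
        profile_a = rng.poisson(20.0, 30) + 1.0
        profile_b = rng.poisson(20.0, 30) + 1.0
        counts = np.vstack([rng.poisson(profile_a, (20, 30)),
                            rng.poisson(profile_b, (20, 30))])
        asn, m = _assignment([1] * 20 + [2] * 20, counts)
        types = pd.Series(["A"] * 20 + ["B"] * 20,
                          index=[f"b{i}" for i in range(40)])
        table = celltype_metacell_correlation(asn, m, types).set_index(
            ["cell_type", "metacell"])
        assert table.loc[("A", 1), "r"] > table.loc[("A", 2), "r"]
        assert table.loc[("A", 1), "r"] > 0.9

    def test_constant_profile_gives_missing(self):
        counts = np.ones((4, 5))
        asn, m = _assignment([1, 1, 2, 2], counts)
        types = pd.Series(["A"] * 4, index=[f"b{i}" for i in range(4)])
        table = celltype_metacell_correlation(asn, m, types)
        assert table["r"].isna().all()


def _modules(assignment, assoc_rows):
    a = pd.DataFrame(assoc_rows, columns=["module", "tissue", "overlap",
                                          "module_size", "tissue_total", "p"])
    a["fdr"] = a["p"]
    a["associated"] = a["fdr"] < 0.05
    return ModulePartition(pd.Series(assignment), a)


class TestSignatures:
    def test_disjoint_modules_give_disjoint_signatures(self):
        modules = _modules({1: 1, 2: 2},
                           [(1, "liver", 1, 1, 1, 0.01),
                            (2, "lung", 1, 1, 1, 0.01)])
        sets = {1: AccessibleSet("1", frozenset({"p1", "p2"}), 0.05),
                2: AccessibleSet("2", frozenset({"p3"}), 0.05)}
        sigs = build_tissue_signatures(modules, sets)
        assert sigs["liver"] == {"p1", "p2"}
        assert sigs["lung"] == {"p3"}

    def test_shared_peaks_are_stripped_as_uninformative(self):
        modules = _modules({1: 1, 2: 2},
                           [(1, "liver", 1, 1, 1, 0.01),
                            (2, "lung", 1, 1, 1, 0.01)])
        sets = {1: AccessibleSet("1", frozenset({"hk", "p1"}), 0.05),
                2: AccessibleSet("2", frozenset({"hk", "p2"}), 0.05)}
        sigs = build_tissue_signatures(modules, sets)
        assert sigs["liver"] == {"p1"} and sigs["lung"] == {"p2"}

    def test_fallback_capped_at_limit(self):
        rng = np.random.default_rng(2)
        modules = _modules({1: 1}, [(1, "liver", 1, 1, 1, 0.01),
                                    (1, "lung", 0, 1, 1, 0.9)])
        sets = {1: AccessibleSet("1", frozenset({"p0"}), 0.05)}
        counts = rng.poisson(1.0, size=(40, 30)).astype(float)
        pm = FeatureMatrix(sp.csr_matrix(counts),
                          [f"b{i}" for i in range(40)],
                          [f"p{j}" for j in range(30)], "peak")
        tissues = pd.Series(np.repeat(["liver", "lung"], 20),
                            index=pm.barcodes)
        sigs = build_tissue_signatures(modules, sets, peak_matrix=pm,
                                       tissue_of=tissues, fallback_top=5)
        assert len(sigs["lung"]) <= 5


class TestPredictOrigin:
    def _pm(self, rows):
        vals = np.asarray(rows, float)
        return FeatureMatrix(sp.csr_matrix(vals),
                            [f"b{i}" for i in range(vals.shape[0])],
                            [f"p{j}" for j in range(vals.shape[1])], "peak")

    def test_subset_profile_predicts_owner(self):
        sigs = {"liver": frozenset({"p0", "p1"}), "lung": frozenset({"p2"})}
        pm = self._pm([[1, 1, 0], [0, 0, 3]])
        out = predict_origin(pm, sigs)
        assert list(out["predicted_tissue"]) == ["liver", "lung"]

    def test_empty_profile_unclassified(self):
        sigs = {"liver": frozenset({"p0"}), "lung": frozenset({"p1"})}
        out = predict_origin(self._pm([[0, 0]]), sigs)
        assert out["predicted_tissue"].isna().all()

    def test_tie_gives_no_call(self):
        sigs = {"liver": frozenset({"p0"}), "lung": frozenset({"p1"})}
        out = predict_origin(self._pm([[1, 1]]), sigs)
        assert out["predicted_tissue"].isna().all()

    def test_accuracy_over_called_cells(self):
        preds = pd.DataFrame({"barcode": ["a", "b", "c"],
                              "predicted_tissue": ["x", "y", None],
                              "score": [1, 1, 0]})
        truth = pd.Series({"a": "x", "b": "x", "c": "x"})
        assert prediction_accuracy(preds, truth) == pytest.approx(0.5)

    def test_holdout_split_disjoint_and_seeded(self):
        barcodes = [f"b{i}" for i in range(100)]
        tr1, te1 = holdout_split(barcodes, 0.5, seed=4)
        tr2, te2 = holdout_split(barcodes, 0.5, seed=4)
        assert tr1 == tr2 and te1 == te2
        assert not set(tr1) & set(te1)
        assert len(tr1) + len(te1) == 100


class TestGate:
    def test_zero_thresholds_select_all_positive(self):
        region = pd.Series([1.0, 2.0], index=["a", "b"])
        gene = pd.Series([0.5, 3.0], index=["a", "b"])
        assert list(combinatorial_gate(region, gene, 0.0, 0.0)) == ["a", "b"]

    def test_infinite_gene_threshold_selects_none(self):
        region = pd.Series([1.0], index=["a"])
        gene = pd.Series([5.0], index=["a"])
        assert len(combinatorial_gate(region, gene, 0.0, np.inf)) == 0

    def test_gate_is_intersection_of_strict_thresholds(self):
        region = pd.Series([1.0, 5.0, 5.0], index=list("abc"))
        gene = pd.Series([5.0, 1.0, 5.0], index=list("abc"))
        assert list(combinatorial_gate(region, gene, 2.0, 2.0)) == ["c"]


class TestMarkerCorrelation:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        rho, _ = marker_correlation(x, x**3)
        assert rho == pytest.approx(1.0)
        rho, _ = marker_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_t_approximation_close_to_exact_permutation_at_n5(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x, y = rng.normal(size=5), rng.normal(size=5)
            rho, p_exact = marker_correlation(x, y)  # permutation p at n<=8
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            r = np.corrcoef(rx, ry)[0, 1]
            t = r * np.sqrt(3 / max(1 - r**2, 1e-12))
            p_t = 2 * stats.t.sf(abs(t), df=3)
            # the t reference is only an approximation at n=5; the measured
            # worst-case gap to the exact permutation p is just under 0.08
            assert abs(p_exact - min(p_t, 1.0)) < 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            marker_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
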