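"""NMF factorization, top-gene selection, module matching, projection."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from _oracles import best_overlap_match, longest_dominating_prefix

from hexseq import modules_nmf
from hexseq.modules_nmf import (GeneModuleSet, celltype_fractions, factorize,
                                match_modules, project_module,
                                top_contributing_genes)


def _module_set(basis_array, genes=None):
    genes = genes or [f"g{i}" for i in range(basis_array.shape[0])]
    basis = pd.DataFrame(basis_array, index=genes,
                         columns=[f"M{m}" for m in range(basis_array.shape[1])])
    return GeneModuleSet(basis=basis, usage=np.zeros((basis.shape[1], 1)),
                         objective_trace=np.array([0.0]))


class TestFactorize:
    def test_planted_rank2_reconstruction(self, rng):
        W = rng.uniform(0, 1, (60, 2))
        H = rng.uniform(0, 1, (2, 80))
        X = pd.DataFrame(W @ H, index=[f"g{i}" for i in range(60)])
        mods = factorize(X, rank=2, seed=0, max_iter=3000, tol=1e-14)
        rel = mods.objective_trace[-1] / np.linalg.norm(X.to_numpy(), "fro")
        assert rel < 1e-3

    def test_rank1_recovery_up_to_scale(self, rng):
        w = rng.uniform(0.1, 1, 30)
        h = rng.uniform(0.1, 1, 40)
        X = pd.DataFrame(np.outer(w, h))
        mods = factorize(X, rank=1, seed=1, max_iter=2000, tol=1e-14)
        w_hat = mods.basis.to_numpy().ravel()
        cos = w_hat @ w / (np.linalg.norm(w_hat) * np.linalg.norm(w))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_objective_non_increasing(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (50, 40)))
        mods = factorize(X, rank=5, seed=2, max_iter=200)
        assert np.all(np.diff(mods.objective_trace) <= 1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            factorize(pd.DataFrame([[1.0, -0.1]]), rank=1)

    def test_deterministic_given_seed(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (30, 20)))
        a = factorize(X, rank=3, seed=7, max_iter=50)
        b = factorize(X, rank=3, seed=7, max_iter=50)
        assert np.array_equal(a.basis.to_numpy(), b.basis.to_numpy())

    def test_matches_sklearn_quality(self, rng):
        """Independent cross-check: final Frobenius error comparable to
        scikit-learn's multiplicative-update solver."""
        from sklearn.decomposition import NMF
        X = rng.uniform(0, 1, (40, 30))
        mods = factorize(pd.DataFrame(X), rank=4, seed=0, max_iter=1000,
                         tol=1e-12)
        sk = NMF(n_components=4, solver="mu", init="random", random_state=0,
                 max_iter=1000, tol=1e-12).fit(X)
        sk_err = np.linalg.norm(X - sk.transform(X) @ sk.components_, "fro")
        assert mods.objective_trace[-1] <= sk_err * 1.05

    def test_smoothing_variant_runs(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (30, 20)))
        mods = factorize(X, rank=3, seed=0, smoothing=0.3, max_iter=100)
        assert (mods.basis.to_numpy() >= 0).all()


class TestTopContributingGenes:
    def test_constructed_prefix_of_three(self):
        basis = np.array([
            [9.0, 1.0], [8.0, 2.0], [7.0, 1.0],  # ranked 1-3, dominate M0
            [6.0, 6.5],                           # rank 4 peaks in M1
            [5.0, 1.0],                           # dominates but after break
        ])
        mods = _module_set(basis)
        assert top_contributing_genes(mods, 0) == ["g0", "g1", "g2"]

    def test_fully_dominating_module(self):
        basis = np.array([[5.0, 1.0], [4.0, 0.5], [3.0, 2.0]])
        mods = _module_set(basis)
        assert top_contributing_genes(mods, 0) == ["g0", "g1", "g2"]

    def test_dominated_module_empty(self):
        basis = np.array([[5.0, 6.0], [4.0, 5.0]])
        mods = _module_set(basis)
        assert top_contributing_genes(mods, 0) == []

    def test_ties_break_the_prefix(self):
        basis = np.array([[5.0, 5.0], [4.0, 1.0]])
        mods = _module_set(basis)
        assert top_contributing_genes(mods, 0) == []

    def test_matches_brute_force_on_random_bases(self, rng):
        for _ in range(20):
            basis_arr = rng.uniform(0, 1, (50, 4))
            mods = _module_set(basis_arr)
            for m in range(4):
                expect = longest_dominating_prefix(mods.basis,
                                                   mods.sorted_genes[m], m)
                assert top_contributing_genes(mods, m) == expect

    def test_output_is_prefix_of_ranking(self, rng):
        basis_arr = rng.uniform(0, 1, (30, 3))
        mods = _module_set(basis_arr)
        for m in range(3):
            top = top_contributing_genes(mods, m)
            assert top == mods.sorted_genes[m][:len(top)]


class TestMatchModules:
    def _random_set(self, rng, n_genes=300, rank=3):
        return _module_set(rng.uniform(0, 1, (n_genes, rank)))

    def test_identical_sets_match_themselves(self, rng):
        s = self._random_set(rng)
        matches = match_modules(s, s, top_n=200)
        assert [(m.module_a, m.module_b, m.overlap_count) for m in matches] \
            == [(0, 0, 200), (1, 1, 200), (2, 2, 200)]

    def test_disjoint_top_sets_unmatched(self):
        a = _module_set(np.diag([1.0] * 4)[:, :2],
                        genes=[f"a{i}" for i in range(4)])
        b = _module_set(np.diag([1.0] * 4)[:, :2],
                        genes=[f"b{i}" for i in range(4)])
        assert match_modules(a, b, top_n=4) == []

    def test_quarter_overlap_boundary_retained(self):
        rng = np.random.default_rng(0)
        shared = [f"s{i}" for i in range(50)]
        only_a = [f"a{i}" for i in range(150)]
        only_b = [f"b{i}" for i in range(150)]
        genes_a = shared + only_a
        genes_b = shared + only_b
        a = _module_set(rng.uniform(0.5, 1, (200, 1)), genes=genes_a)
        b = _module_set(rng.uniform(0.5, 1, (200, 1)), genes=genes_b)
        matches = match_modules(a, b, top_n=200, min_frac=0.25)
        assert len(matches) == 1
        assert matches[0].overlap_fraction == pytest.approx(0.25)

    def test_matches_brute_force(self, rng):
        a = self._random_set(rng, 120, 4)
        b = self._random_set(rng, 120, 4)
        top_n = 30
        got = match_modules(a, b, top_n=top_n, min_frac=0.0)
        tops_a = [a.sorted_genes[m][:top_n] for m in range(4)]
        tops_b = [b.sorted_genes[m][:top_n] for m in range(4)]
        expect = best_overlap_match(tops_a, tops_b, top_n)
        assert [(m.module_a, m.module_b, m.overlap_count) for m in got] == expect


class TestCelltypeFractions:
    def test_exclusive_expression(self):
        expr = pd.DataFrame([[5.0, 0.0], [3.0, 0.0]],
                            index=["g0", "g1"], columns=["c0", "c1"])
        frac = celltype_fractions(expr, ["T1", "T2"], ["g0", "g1"])
        assert frac["T1"] == pytest.approx(1.0)
        assert frac["T2"] == pytest.approx(0.0)

    def test_equal_expression_splits(self):
        expr = pd.DataFrame([[2.0, 2.0]], index=["g0"], columns=["c0", "c1"])
        frac = celltype_fractions(expr, ["T1", "T2"], ["g0"])
        assert np.allclose(frac.to_numpy(), 0.5)

    def test_hand_computed_three_types(self):
        expr = pd.DataFrame(
            [[4.0, 2.0, 0.0], [2.0, 2.0, 2.0], [0.0, 2.0, 4.0]],
            index=["g0", "g1", "g2"], columns=["c0", "c1", "c2"])
        frac = celltype_fractions(expr, ["A", "B", "C"], ["g0", "g1", "g2"])
        # per-type gene means are the columns; medians: A=2, B=2, C=2
        assert np.allclose(frac.to_numpy(), 1 / 3)


class TestProjectModule:
    def _adata(self, values, wells):
        X = sp.csr_matrix(np.asarray(values, dtype=float))
        obs = pd.DataFrame({"well_id": wells},
                           index=[f"c{i}" for i in range(len(wells))])
        return ad.AnnData(X=X, obs=obs,
                          var=pd.DataFrame(index=["g0", "g1"]))

    def test_single_hot_well(self):
        adata = self._adata([[5, 5], [0, 0], [0, 0]], ["w1", "w2", "w3"])
        out = project_module(adata, ["g0", "g1"])
        assert out.loc["w1", "label"] == "high"
        assert set(out.loc[["w2", "w3"], "label"]) == {"none"}

    def test_uniform_expression_none_high(self):
        adata = self._adata([[2, 2]] * 4, ["w1", "w2", "w3", "w4"])
        out = project_module(adata, ["g0", "g1"])
        assert (out["label"] == "low").all()  # equality is not 'above'

    def test_weighted_equals_unweighted_when_constant_cells(self):
        vals = [[1, 1], [3, 3], [5, 5]]
        adata = self._adata(vals, ["w1", "w2", "w3"])
        out = project_module(adata, ["g0", "g1"])
        unweighted = np.mean([1, 3, 5])
        assert (out["mean_expr"] > unweighted).equals(out["label"] == "high")

    def test_scale_invariant_labels(self):
        vals = [[1, 2], [3, 1], [5, 4], [0.5, 0.5]]
        wells = ["w1", "w2", "w3", "w4"]
        a = project_module(self._adata(vals, wells), ["g0", "g1"])
        b = project_module(self._adata(np.array(vals) * 7.5, wells),
                           ["g0", "g1"])
        assert list(a["label"]) == list(b["label"])
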