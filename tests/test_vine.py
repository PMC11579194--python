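"""Vine structure selection, sequential estimation, categorical ordering."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_table
from vinepop.bicop import BivariateCopula, fit_bicop
from vinepop.table import ColumnSpec, CovariateTable
from vinepop.vine import (
    StructureError,
    VineCopulaModel,
    VineEdge,
    VineStructure,
    fit_vine,
    fit_vine_with_categorical,
    loglik_vine,
    select_tree,
)


def brute_force_mst(nodes, W):
    """Maximum spanning tree by enumerating all spanning trees (networkx)."""
    G = nx.Graph()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            G.add_edge(nodes[i], nodes[j], weight=W[i, j])
    best, best_w = None, -np.inf
    idx = {n: i for i, n in enumerate(nodes)}
    for edges in itertools.combinations(G.edges(), len(nodes) - 1):
        T = nx.Graph(edges)
        if T.number_of_nodes() == len(nodes) and nx.is_tree(T):
            w = sum(W[idx[a], idx[b]] for a, b in edges)
            if w > best_w:
                best_w, best = w, {frozenset(e) for e in edges}
    return best, best_w


class TestSelectTree:
    def test_three_node_example(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.6  # AB
        W[1, 2] = W[2, 1] = 0.5  # BC
        W[0, 2] = W[2, 0] = 0.1  # AC
        tree = {frozenset(e) for e in select_tree(["A", "B", "C"], W)}
        assert tree == {frozenset({"A", "B"}), frozenset({"B", "C"})}

    def test_twelve_nodes_give_eleven_edges(self, rng):
        nodes = [f"v{i:02d}" for i in range(12)]
        W = rng.uniform(size=(12, 12))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        assert len(select_tree(nodes, W)) == 11

    def test_two_nodes(self):
        assert select_tree(["a", "b"], np.array([[0, 1.0], [1.0, 0]])) == [("a", "b")]

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            k = int(rng.integers(3, 7))
            nodes = [f"n{i}" for i in range(k)]
            W = rng.uniform(size=(k, k))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            got = {frozenset(e) for e in select_tree(nodes, W)}
            best, best_w = brute_force_mst(nodes, W)
            idx = {n: i for i, n in enumerate(nodes)}
            got_w = sum(W[idx[a], idx[b]] for a, b in (tuple(e) for e in got))
            assert got_w == pytest.approx(best_w)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            select_tree(["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError):
            select_tree(["a", "b"], np.array([[0, np.inf], [np.inf, 0]]))


def markov_chain_table(taus, n, seed, names=None):
    """MVN sample whose copula is a path vine with the given first-tree taus
    (gaussian pair copulas, conditional independence beyond the first tree)."""
    rhos = [math.sin(math.pi * t / 2) for t in taus]
    d = len(taus) + 1
    R = np.eye(d)
    for i in range(d):
        for j in range(i + 1, d):
            R[i, j] = R[j, i] = np.prod(rhos[i:j])
    Z = np.random.default_rng(seed).multivariate_normal(np.zeros(d), R, size=n)
    names = names or [f"x{i}" for i in range(d)]
    return make_table({nm: Z[:, i] for i, nm in enumerate(names)})


class TestFitVine:
    def test_two_covariates_reduce_to_single_bicop(self, rng):
        s = BivariateCopula("gaussian", 0, [0.6]).simulate(2000, seed=1)
        # feed data already on (0,1); marginals are refit but the copula is what matters
        tab = make_table({"u": s[:, 0], "v": s[:, 1]})
        m = fit_vine(tab, family_set=["gaussian"])
        assert len(m.structure.trees) == 1
        edge = m.structure.trees[0][0]
        assert m.loglik == pytest.approx(edge.copula.loglik)
        assert edge.copula.tau() == pytest.approx(2 / math.pi * math.asin(0.6), abs=0.05)

    def test_recovers_known_path_structure(self):
        taus = [0.6, 0.5, 0.4]
        tab = markov_chain_table(taus, 5000, seed=42, names=list("ABCD"))
        m = fit_vine(tab, family_set=["gaussian"])
        got = {e.conditioned for e in m.first_tree_edges()}
        assert got == {("A", "B"), ("B", "C"), ("C", "D")}
        by_pair = {e.conditioned: e.copula.tau() for e in m.first_tree_edges()}
        for pair, t in zip([("A", "B"), ("B", "C"), ("C", "D")], taus):
            assert by_pair[pair] == pytest.approx(t, abs=0.05)

    def test_structure_invariants_on_fitted_model(self):
        tab = markov_chain_table([0.5, 0.4, 0.3, 0.2], 1000, seed=3)
        m = fit_vine(tab, family_set=["gaussian"])
        m.structure.validate()  # proximity + edge counts + acyclicity
        d = len(m.variables)
        for t, tree in enumerate(m.structure.trees, start=1):
            assert len(tree) == d - t
            for e in tree:
                assert len(e.conditioning) == t - 1

    def test_missing_data_taus_close_to_complete_fit(self):
        tab = markov_chain_table([0.6, 0.5, 0.4], 4000, seed=11, names=list("ABCD"))
        m_full = fit_vine(tab, family_set=["gaussian"])
        df = tab.df.copy()
        drop = np.random.default_rng(12).uniform(size=len(df)) < 0.3
        df.loc[drop, "B"] = np.nan
        m_miss = fit_vine(CovariateTable(df=df, columns=tab.columns), family_set=["gaussian"])
        tau_full = {e.conditioned: e.copula.tau() for e in m_full.first_tree_edges()}
        tau_miss = {e.conditioned: e.copula.tau() for e in m_miss.first_tree_edges()}
        for pair in tau_full:
            if pair in tau_miss:
                assert tau_miss[pair] == pytest.approx(tau_full[pair], abs=0.07)

    def test_unit_weights_reproduce_unweighted_fit(self):
        tab = markov_chain_table([0.5, 0.3], 800, seed=5)
        m0 = fit_vine(tab, family_set=["gaussian", "frank"])
        m1 = fit_vine(tab, family_set=["gaussian", "frank"], weights=np.ones(800))
        for t0, t1 in zip(m0.structure.trees, m1.structure.trees):
            for e0, e1 in zip(t0, t1):
                assert e0.conditioned == e1.conditioned
                assert e0.copula.family == e1.copula.family
                assert np.allclose(e0.copula.parameters, e1.copula.parameters)

    def test_single_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_vine(make_table({"x": rng.standard_normal(100)}))

    def test_too_few_values_named(self, rng):
        df = {"x": rng.standard_normal(100), "y": np.full(100, np.nan)}
        df["y"][:5] = rng.standard_normal(5)
        with pytest.raises(Exception, match="y"):
            fit_vine(make_table(df))


class TestLoglik:
    def test_independence_vine_loglik_zero(self, rng):
        tab = make_table({"a": rng.standard_normal(300), "b": rng.standard_normal(300),
                          "c": rng.standard_normal(300)})
        m = fit_vine(tab, family_set=["independence"])
        assert m.loglik == 0.0
        assert loglik_vine(m, tab) == pytest.approx(0.0)

    def test_evaluated_loglik_matches_fit(self):
        tab = markov_chain_table([0.5, 0.4], 1500, seed=8)
        m = fit_vine(tab, family_set=["gaussian"])
        assert loglik_vine(m, tab) == pytest.approx(m.loglik, rel=1e-8)

    def test_fitted_aic_beats_independence_vine(self):
        tab = markov_chain_table([0.6, 0.5], 1500, seed=9)
        m = fit_vine(tab)
        m_ind = fit_vine(tab, family_set=["independence"])
        assert m.aic <= m_ind.aic

    def test_schema_mismatch_raises(self, rng):
        tab = markov_chain_table([0.5], 300, seed=10)
        other = make_table({"p": rng.standard_normal(100), "q": rng.standard_normal(100)})
        m = fit_vine(tab, family_set=["gaussian"])
        with pytest.raises(ValueError, match="match"):
            loglik_vine(m, other)


class TestCategoricalOrderSearch:
    @staticmethod
    def _mixed_table(n, k, seed):
        r = np.random.default_rng(seed)
        z = r.standard_normal(n)
        levels = [f"L{i}" for i in range(k)]
        labels = np.array(levels, dtype=object)[np.minimum((stats.norm.cdf(z + 0.8 * r.standard_normal(n)) * k).astype(int), k - 1)]
        return make_table({"g": labels, "x": z + 0.3 * r.standard_normal(n)},
                          kinds={"g": "categorical"})

    def test_three_levels_six_candidates(self):
        tab = self._mixed_table(400, 3, seed=1)
        m = fit_vine_with_categorical(tab, "g", family_set=["gaussian"])
        assert m.n_candidates == 6
        assert sorted(m.categorical_order["g"]) == ["L0", "L1", "L2"]

    def test_single_level_trivial(self, rng):
        tab = make_table({"g": np.array(["only"] * 200, dtype=object),
                          "x": rng.standard_normal(200)}, kinds={"g": "categorical"})
        m = fit_vine_with_categorical(tab, "g", family_set=["gaussian"])
        assert m.n_candidates == 1

    def test_too_many_levels_refused(self, rng):
        labels = np.array([f"L{i % 8}" for i in range(400)], dtype=object)
        tab = make_table({"g": labels, "x": rng.standard_normal(400)}, kinds={"g": "categorical"})
        with pytest.raises(ValueError, match="pre-specify"):
            fit_vine_with_categorical(tab, "g")

    def test_search_improves_or_matches_default_order(self):
        tab = self._mixed_table(600, 3, seed=4)
        searched = fit_vine_with_categorical(tab, "g", family_set=["gaussian"])
        default = fit_vine(tab, family_set=["gaussian"])
        assert searched.aic <= default.aic + 1e-9


class TestStructureValidation:
    def test_detects_wrong_edge_count(self):
        s = VineStructure(variables=["a", "b", "c"], trees=[[VineEdge(("a", "b"), frozenset())]])
        with pytest.raises(StructureError):
            s.validate()

    def test_detects_cycle(self):
        edges = [VineEdge(("a", "b"), frozenset()), VineEdge(("a", "b"), frozenset()),
                 VineEdge(("c", "d"), frozenset())]
        s = VineStructure(variables=["a", "b", "c", "d"],
                          trees=[edges, [VineEdge(("c", "d"), frozenset({"a"}))],
                                 [VineEdge(("a", "d"), frozenset({"b", "c"}))]])
        with pytest.raises(StructureError):
            s.validate()

    def test_detects_proximity_violation(self):
        t1 = [VineEdge(("a", "b"), frozenset()), VineEdge(("b", "c"), frozenset()),
              VineEdge(("c", "d"), frozenset())]
        # a,d | b is not allowed: edges (a,b) and (c,d) share no node
        t2 = [VineEdge(("a", "d"), frozenset({"b"})), VineEdge(("a", "c"), frozenset({"b"}))]
        t3 = [VineEdge(("c", "d"), frozenset({"a", "b"}))]
        s = VineStructure(variables=["a", "b", "c", "d"], trees=[t1, t2, t3])
        with pytest.raises(StructureError):
            s.validate()


class TestSerialization:
    def test_model_json_roundtrip(self, tmp_path):
        tab = markov_chain_table([0.5, 0.4], 800, seed=13)
        m = fit_vine(tab, family_set=["gaussian", "clayton"])
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = VineCopulaModel.from_json(path)
        assert m2.loglik == pytest.approx(m.loglik)
        assert m2.aic == pytest.approx(m.aic)
        assert [e.label() for t in m2.structure.trees for e in t] == [
            e.label() for t in m.structure.trees for e in t
        ]
        from vinepop.simulate import simulate

        s1 = simulate(m, 100, seed=77)
        s2 = simulate(m2, 100, seed=77)
        pd.testing.assert_frame_equal(s1.df, s2.df)

    def test_truncated_fit_has_independence_upper_trees(self):
        tab = markov_chain_table([0.6, 0.5, 0.4], 1500, seed=14)
        m = fit_vine(tab, family_set=["gaussian"], truncation=1)
        for tree in m.structure.trees[1:]:
            assert all(e.copula.family == "independence" for e in tree)
        assert all(e.copula.family != "independence" or abs(e.tau_emp) < 0.1
                   for e in m.structure.trees[0])
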