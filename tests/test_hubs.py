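"""Unit tests for MCODE and the hub centralities, against brute-force oracles."""
import itertools
import math

import networkx as nx
import numpy as np
import pytest

from ddcpredict.config import McodeParams
from ddcpredict.hubs import (
    centrality_scores,
    mcode_modules,
    module_score,
    select_ddgs,
    top_k_aggregate,
    McodeModule,
)
from ddcpredict.synthetic import simulate_network


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def brute_mcc(g, v):
    """Sum of (|C|-1)! over maximal cliques containing v, by subset enumeration."""
    nodes = list(g.nodes())
    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques
               if not any(c < d for d in cliques)]
    return sum(math.factorial(len(c) - 1) for c in maximal if v in c)


def brute_mnc_dmnc(g, v, eps=1.7):
    nb = set(g[v])
    if not nb:
        return 0, 0.0
    sub = g.subgraph(nb)
    comps = list(nx.connected_components(sub))
    best = max(comps, key=lambda c: (len(c), sub.subgraph(c).number_of_edges()))
    e = sub.subgraph(best).number_of_edges()
    return len(best), e / len(best) ** eps


class TestCentralityHandExamples:
    def test_triangle(self):
        g = nx.complete_graph(3)
        assert centrality_scores(g, "degree") == {0: 2, 1: 2, 2: 2}
        assert centrality_scores(g, "mnc") == {0: 2, 1: 2, 2: 2}
        dmnc = centrality_scores(g, "dmnc")
        assert dmnc[0] == pytest.approx(1 / 2**1.7)
        assert centrality_scores(g, "mcc") == {0: 2.0, 1: 2.0, 2: 2.0}

    def test_path(self):
        g = nx.path_graph(3)  # a - b - c
        mcc = centrality_scores(g, "mcc")
        assert mcc[1] == 2.0  # 1! + 1!
        assert mcc[0] == 1.0
        assert centrality_scores(g, "mnc")[1] == 1  # two isolated neighbors

    def test_isolated_node_mcc_convention(self):
        g = nx.Graph()
        g.add_node("lonely")
        assert centrality_scores(g, "mcc")["lonely"] == 1.0  # 0! = 1

    def test_epc_no_percolation_on_complete_graph(self):
        g = nx.complete_graph(6)
        epc = centrality_scores(g, "epc", epc_iters=5, retention_prob=1.0)
        assert all(v == 6.0 for v in epc.values())

    def test_epc_deterministic_given_seed(self):
        g = nx.gnp_random_graph(20, 0.2, seed=1)
        a = centrality_scores(g, "epc", epc_iters=50, seed=9)
        b = centrality_scores(g, "epc", epc_iters=50, seed=9)
        assert a == b

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            centrality_scores(nx.path_graph(2), "pagerank")


class TestCentralityOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_brute_force(self, seed):
        g = nx.gnp_random_graph(7, 0.45, seed=seed)
        mcc = centrality_scores(g, "mcc")
        mnc = centrality_scores(g, "mnc")
        dmnc = centrality_scores(g, "dmnc")
        for v in g.nodes():
            assert mcc[v] == pytest.approx(brute_mcc(g, v))
            bm, bd = brute_mnc_dmnc(g, v)
            assert mnc[v] == bm
            assert dmnc[v] == pytest.approx(bd)

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(10, 0.3, seed=3)
        mapping = {v: f"gene{v}" for v in g.nodes()}
        h = nx.relabel_nodes(g, mapping)
        for method in ("degree", "mnc", "dmnc", "mcc"):
            a = centrality_scores(g, method)
            b = centrality_scores(h, method)
            assert all(b[mapping[v]] == pytest.approx(a[v]) for v in g.nodes())

    def test_epc_monotone_under_edge_addition(self):
        g = nx.path_graph(8)
        sparse = np.mean(list(centrality_scores(g, "epc", epc_iters=200, seed=0).values()))
        g2 = g.copy()
        g2.add_edges_from([(0, 4), (1, 5), (2, 6)])
        dense = np.mean(list(centrality_scores(g2, "epc", epc_iters=200, seed=0).values()))
        assert dense >= sparse


class TestMcode:
    def test_isolated_clique_found_exactly(self):
        g = nx.complete_graph(6)
        g.add_nodes_from(range(6, 12))
        mods = mcode_modules(g)
        assert len(mods) == 1
        assert mods[0].nodes == frozenset(range(6))
        assert mods[0].score == pytest.approx(6.0)

    def test_two_disjoint_cliques_scored_by_size(self):
        g = nx.disjoint_union(nx.complete_graph(8), nx.complete_graph(5))
        mods = mcode_modules(g)
        assert sorted(m.score for m in mods) == [5.0, 8.0]
        # only the size-8 clique passes the score>3 AND nodes>5 signature criteria
        passing = [m for m in mods if m.score > 3 and m.n_nodes > 5]
        assert len(passing) == 1 and passing[0].n_nodes == 8

    def test_empty_edge_graph_yields_no_modules(self):
        g = nx.empty_graph(10)
        assert mcode_modules(g) == []

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcode_modules(nx.Graph())

    def test_disjoint_cliques_recovered_exactly(self):
        g = nx.disjoint_union_all([nx.complete_graph(k) for k in (4, 6, 9)])
        mods = mcode_modules(g)
        sizes = sorted(m.n_nodes for m in mods)
        assert sizes == [4, 6, 9]
        for m in mods:
            assert m.score == pytest.approx(m.n_nodes)  # density-1 score = size

    def test_planted_module_recovery_with_background(self):
        hits = []
        for seed in range(10):
            g, truth = simulate_network(
                n_nodes=200, background_p=0.02, planted_clique_sizes=(8, 6), seed=seed
            )
            mods = mcode_modules(g)
            for planted, _ in truth.planted_modules:
                best = max(
                    (len(planted & m.nodes) / len(planted | m.nodes) for m in mods),
                    default=0.0,
                )
                hits.append(best >= 0.8)
        assert np.mean(hits) >= 0.8


class TestSelectDdgs:
    def _mod(self, genes, score):
        return McodeModule(nodes=frozenset(genes), score=score, seed_node=sorted(genes)[0])

    def test_union_of_passing_modules(self):
        up = [self._mod([f"u{i}" for i in range(12)], 5.2)]
        down = [self._mod([f"d{i}" for i in range(7)], 3.5)]
        sig = select_ddgs(up, down)
        assert len(sig["DDG"]) == 19
        assert set(sig["DDG_up"]) == {f"u{i}" for i in range(12)}

    def test_failing_direction_dropped_with_warning(self):
        up = [self._mod([f"u{i}" for i in range(12)], 5.2)]
        down = [self._mod([f"d{i}" for i in range(7)], 2.9)]
        with pytest.warns(UserWarning):
            sig = select_ddgs(up, down)
        assert "DDG_down" not in sig.sets
        assert set(sig["DDG"]) == set(sig["DDG_up"])

    def test_both_directions_failing_is_error(self):
        weak = [self._mod(["a", "b", "c", "d"], 2.0)]
        with pytest.raises(ValueError):
            select_ddgs(weak, weak)


class TestTopKAggregate:
    def _tables(self, scores_by_gene):
        # same score table for every method unless overridden
        return {m: dict(scores_by_gene) for m in ("degree", "mnc", "dmnc", "mcc", "epc")}

    def test_selected_count_reaches_five(self):
        tables = self._tables({f"g{i}": 20 - i for i in range(15)})
        agg = top_k_aggregate(tables, k=10, min_degree=0)
        assert agg.table.at["g0", "selected_count"] == 5

    def test_low_degree_gene_excluded_everywhere(self):
        tables = self._tables({f"g{i}": float(20 - i) for i in range(12)})
        tables["mcc"]["g11"] = 100.0   # highest MCC ...
        tables["degree"]["g11"] = 9.0  # ... but degree < 10
        agg = top_k_aggregate(tables, k=10, min_degree=10)
        assert agg.table.at["g11", "selected_count"] == 0

    def test_tie_broken_by_degree(self):
        scores = {f"g{i}": float(30 - i) for i in range(9)}
        scores.update({"tieA": 1.0, "tieB": 1.0})
        tables = self._tables(scores)
        tables["degree"].update({"tieA": 12.0, "tieB": 11.0})
        agg = top_k_aggregate(tables, k=10, min_degree=0)
        assert bool(agg.table.at["tieA", "in_top_mnc"])
        assert not bool(agg.table.at["tieB", "in_top_mnc"])

    def test_k_clamped_with_warning(self):
        tables = self._tables({"a": 1.0, "b": 2.0})
        with pytest.warns(UserWarning):
            agg = top_k_aggregate(tables, k=10, min_degree=0)
        assert agg.k == 2
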