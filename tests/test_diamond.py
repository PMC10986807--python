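"""Connectivity-significance module detection and grid-search selection."""

import math
from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from proteoscreen.diamond import (biological_validation_pvalue,
                                  connectivity_pvalue, grid_search,
                                  hypergeom_tail, run_diamond)
from proteoscreen.simulate import generate_interactome


def brute_tail(N, K, n, k_min):
    """Exact rational hypergeometric tail."""
    total = Fraction(0)
    for i in range(max(k_min, 0), min(n, K) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i),
                          math.comb(N, n))
    return min(total, Fraction(1))


def oracle_diamond(graph, seeds, n_iter):
    """Brute-force re-derivation: recompute every candidate's tail each
    step with exact rational arithmetic, same tie-breaking."""
    module = set(seeds)
    N = graph.number_of_nodes()
    added = []
    for _ in range(n_iter):
        cands = []
        for node in graph.nodes:
            if node in module:
                continue
            k = graph.degree(node)
            ks = sum(1 for nb in graph.neighbors(node) if nb in module)
            if ks == 0:
                continue
            p = brute_tail(N, len(module), k, ks)
            cands.append((p, -ks, -k, str(node)))
        if not cands:
            break
        cands.sort()
        added.append(cands[0][3])
        module.add(cands[0][3])
    return added


class TestConnectivityPvalue:
    def test_worked_case_one_third(self):
        # N=10, s0=3, k=4, ks=2, alpha=1: (C(3,2)C(7,2)+C(3,3)C(7,1))/C(10,4)
        g = nx.Graph()
        g.add_nodes_from(range(10))
        module = {0, 1, 2}
        g.add_edges_from([(9, 0), (9, 1), (9, 3), (9, 4)])
        cs = connectivity_pvalue(g, module, 9, alpha=1)
        assert (cs.k, cs.ks) == (4, 2)
        assert cs.p == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_no_links_to_module_gives_p_one(self):
        g = nx.path_graph(6)
        cs = connectivity_pvalue(g, {0}, 5, alpha=1)
        assert cs.ks == 0
        assert cs.p == pytest.approx(1.0)

    def test_all_links_to_seeds_is_most_significant(self):
        # same degree k: the more links land in the module, the smaller p
        for N, s0, k in [(12, 4, 3), (20, 5, 4), (15, 6, 5)]:
            ps = [float(brute_tail(N, s0, k, ks)) for ks in range(k + 1)]
            assert all(ps[i + 1] < ps[i] for i in range(k))
            assert hypergeom_tail(N, s0, k, k) == pytest.approx(
                ps[-1], rel=1e-10)

    def test_candidate_in_module_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError):
            connectivity_pvalue(g, {0, 1}, 1, alpha=1)

    def test_seed_weighting_boosts_seed_links(self):
        g = nx.Graph()
        g.add_nodes_from(range(30))
        module = set(range(5))
        g.add_edges_from([(20, 0), (20, 1), (20, 10), (20, 11)])
        p1 = connectivity_pvalue(g, module, 20, alpha=1).p
        p3 = connectivity_pvalue(g, module, 20, alpha=3).p
        assert p3 < p1

    def test_exhaustive_exact_enumeration_small_n(self):
        for N in range(2, 16):
            for s0 in range(1, N):
                for k in range(1, N):
                    for ks in range(0, min(k, s0) + 1):
                        got = hypergeom_tail(N, s0, k, ks)
                        want = float(brute_tail(N, s0, k, ks))
                        assert got == pytest.approx(want, rel=1e-10,
                                                    abs=1e-14)


class TestRunDiamond:
    def test_single_iteration_adds_one_node(self):
        g = nx.barbell_graph(4, 2)
        mod = run_diamond(g, {0, 1}, 1, alpha=1)
        assert len(mod.added) == 1
        assert mod.added_nodes[0] not in {0, 1}

    def test_triangle_seed_with_triple_linked_neighbour_wins(self):
        g = nx.Graph()
        seeds = {"A", "B", "C"}
        g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
        g.add_edges_from([("W", "A"), ("W", "B"), ("W", "C")])
        for i, s in enumerate(["A", "B", "C"] * 2):
            g.add_edge(f"X{i}", s)
        mod = run_diamond(g, seeds, 1, alpha=1)
        assert mod.added_nodes == ["W"]

    def test_matches_bruteforce_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(6, 16))
            g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.5)),
                                    seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            seeds = set(rng.choice(sorted(g.nodes),
                                   int(rng.integers(1, 4)), replace=False))
            n_iter = int(rng.integers(1, 6))
            assert run_diamond(g, seeds, n_iter).added_nodes == \
                oracle_diamond(g, seeds, n_iter)

    def test_greedy_nestedness_in_n(self):
        g = generate_interactome(120, 3, ["S1", "S2", "S3"], rng_seed=4,
                                 protein_ids=["S1", "S2", "S3"])
        full = run_diamond(g, {"S1", "S2", "S3"}, 30, alpha=2)
        short = run_diamond(g, {"S1", "S2", "S3"}, 12, alpha=2)
        assert full.added_nodes[:12] == short.added_nodes

    def test_deterministic_under_node_insertion_order(self):
        g = generate_interactome(80, 2, ["S1", "S2"], rng_seed=9,
                                 protein_ids=["S1", "S2"])
        h = nx.Graph()
        for a, b in sorted(g.edges, reverse=True):
            h.add_edge(a, b)
        assert run_diamond(g, {"S1", "S2"}, 15).added_nodes == \
            run_diamond(h, {"S1", "S2"}, 15).added_nodes

    def test_frontier_exhaustion_flagged(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("C", "D")])
        mod = run_diamond(g, {"A"}, 3, alpha=1)
        assert mod.exhausted
        assert mod.added_nodes == ["B"]

    def test_unknown_seed_rejected(self):
        with pytest.raises(ValueError, match="NOPE"):
            run_diamond(nx.path_graph(4), {0, "NOPE"}, 1)

    def test_hub_ranking_is_stable_and_complete(self):
        g = generate_interactome(100, 3, ["S1", "S2"], rng_seed=2,
                                 protein_ids=["S1", "S2"])
        mod = run_diamond(g, {"S1", "S2"}, 10)
        ranks = mod.hub_ranking(g)
        assert set(ranks.node) == set(mod.nodes)
        assert (ranks.module_degree.diff().dropna() <= 0).all()


class TestValidationAndGrid:
    def test_module_disjoint_from_validation_gives_p_one(self):
        g = nx.path_graph(12)
        mod = run_diamond(g, {0}, 2)
        p = biological_validation_pvalue(mod, {9, 10, 11}, set(g.nodes))
        assert p == pytest.approx(1.0)

    def test_validation_superset_reaches_minimum_achievable_p(self):
        g = nx.complete_graph(8)
        mod = run_diamond(g, {0, 1}, 2)
        nodes = set(mod.nodes)
        p = biological_validation_pvalue(mod, nodes, set(g.nodes))
        want = brute_tail(8, len(nodes), len(nodes), len(nodes))
        assert p == pytest.approx(float(want), rel=1e-9)

    def test_inert_background_strictly_decreases_p(self):
        g = nx.complete_graph(10)
        mod = run_diamond(g, {0, 1}, 3)
        background = set(g.nodes)
        val = set(mod.nodes)
        p_small = biological_validation_pvalue(mod, val, background)
        p_big = biological_validation_pvalue(
            mod, val, background | {f"Z{i}" for i in range(10)})
        assert p_big < p_small

    def test_grid_of_one_returns_only_candidate(self):
        g = generate_interactome(60, 2, ["S1", "S2"], rng_seed=3,
                                 protein_ids=["S1", "S2"])
        best, table = grid_search(g, {"S1", "S2"}, [5], [2],
                                  set(list(g.nodes)[:20]) | {"S1", "S2"},
                                  set(g.nodes))
        assert len(table) == 1
        assert (best.n_requested, best.alpha) == (5, 2)

    def test_table_covers_full_grid(self):
        g = generate_interactome(60, 2, ["S1", "S2"], rng_seed=3,
                                 protein_ids=["S1", "S2"])
        _, table = grid_search(g, {"S1", "S2"}, [5, 10, 15], [1, 2],
                               {"S1", "S2"}, set(g.nodes))
        assert len(table) == 6

    def test_recovers_planted_neighbourhood(self):
        seeds = ["S1", "S2", "S3", "S4"]
        g = generate_interactome(400, 3, seeds, rng_seed=5,
                                 protein_ids=seeds, neighbourhood_size=25)
        nbh = set(g.graph["planted_neighbourhood"])
        best, _ = grid_search(g, set(seeds), [10, 20, 30, 40], [1, 2, 3],
                              nbh | set(seeds), set(g.nodes))
        assert len(set(best.nodes) & nbh) / len(nbh) >= 0.8
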