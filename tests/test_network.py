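"""Shortest-path topology statistics against exhaustive-enumeration oracles."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pmedkit.crossmap import ZProfile
from pmedkit.network import (InteractionNetwork, Pair, build_shortest_path_network,
                             node_pair_probability, pair_counts, run_network_method,
                             seed_pair_universe, select_seed)


def profile(values):
    return ZProfile("t", "human-probe", pd.Series(values, dtype=float))


def net_from_edges(edges, targets=None):
    G = nx.DiGraph()
    G.add_edges_from(edges)
    return InteractionNetwork(G, targets or {})


# ---------------------------------------------------------------------------
# oracles: brute-force path enumeration


def oracle_spn(G, seeds):
    """Shortest-path network via explicit all-shortest-paths enumeration."""
    S = nx.DiGraph()
    for s in seeds:
        for t in seeds:
            if s == t or not nx.has_path(G, s, t):
                continue
            for path in nx.all_shortest_paths(G, s, t):
                S.add_nodes_from(path)
                nx.add_path(S, path)
    return S


def oracle_pair_counts(G, universe):
    """Count universe pairs through each node pair by enumerating paths."""
    counts = {}
    for s, t in universe:
        if s == t or not nx.has_path(G, s, t):
            continue
        through = set()
        for path in nx.all_shortest_paths(G, s, t):
            for i, j in combinations(sorted(set(path)), 2):
                through.add(Pair((i, j)))
        for pair in through:
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def oracle_hypergeom_tail(k, M, n, N):
    """Direct combinatorial sum of the upper hypergeometric tail."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
    return total


# ---------------------------------------------------------------------------


class TestSeedSelection:
    def test_threshold_mode(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        zp = profile({"a": 2.5, "b": 1.0, "c": 2.0, "offnet": 9.0})
        seeds = select_seed(zp, net, "threshold")
        assert set(seeds.nodes) == {"a", "c"}

    def test_top_n_mode_with_ties(self):
        net = net_from_edges([(f"n{i}", f"n{i+1}") for i in range(9)])
        z = {f"n{i}": 5.0 for i in range(10)}  # fully tied
        seeds = select_seed(profile(z), net, "top200", top_n=4)
        assert list(seeds.nodes) == ["n0", "n1", "n2", "n3"]  # lexicographic

    def test_top_n_caps_large_seed(self):
        net = net_from_edges([(f"n{i}", f"n{(i+1) % 250}") for i in range(250)])
        z = {f"n{i}": 2.0 + i * 0.001 for i in range(250)}
        seeds = select_seed(profile(z), net, "top200")
        assert len(seeds) == 200


class TestShortestPathNetwork:
    def test_single_path_chain(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        S = build_shortest_path_network(net, ["a", "c"])
        assert set(S.edges) == {("a", "b"), ("b", "c")}

    def test_parallel_equal_paths_both_kept(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "d"), ("d", "c")])
        S = build_shortest_path_network(net, ["a", "c"])
        assert set(S.edges) == {("a", "b"), ("b", "c"), ("a", "d"), ("d", "c")}

    def test_disconnected_seeds_give_empty_network(self):
        net = net_from_edges([("a", "b"), ("c", "d")])
        S = build_shortest_path_network(net, ["a", "c"])
        assert S.number_of_edges() == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        G = nx.gnp_random_graph(n, 0.25, seed=seed + 100, directed=True)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in range(n)})
        G.remove_edges_from(nx.selfloop_edges(G))
        net = InteractionNetwork(G)
        seeds = sorted(rng.choice(sorted(G.nodes), size=min(4, n), replace=False))
        S = build_shortest_path_network(net, seeds)
        O = oracle_spn(G, seeds)
        assert set(S.edges) == set(O.edges)
        # every S edge is a global edge; every S node is on a seed path
        assert set(S.edges) <= set(G.edges)
        assert set(S.nodes) >= set(O.nodes)


class TestPairCounts:
    def test_chain_example(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        counts = pair_counts(net, [("a", "d")])
        assert counts[Pair(("b", "c"))] == 1
        assert counts[Pair(("a", "d"))] == 1

    def test_off_path_node_counts_zero(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("x", "a")])
        counts = pair_counts(net, [("a", "c")])
        assert all("x" not in pair for pair in counts)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed + 50)
        n = int(rng.integers(5, 13))
        G = nx.gnp_random_graph(n, 0.3, seed=seed, directed=True)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in range(n)})
        G.remove_edges_from(nx.selfloop_edges(G))
        net = InteractionNetwork(G)
        universe = [(s, t) for s in G.nodes for t in G.nodes if s != t]
        assert pair_counts(net, universe) == oracle_pair_counts(G, universe)

    @pytest.mark.parametrize("seed", range(4))
    def test_seed_counts_never_exceed_global(self, seed):
        rng = np.random.default_rng(seed)
        G = nx.gnp_random_graph(10, 0.3, seed=seed + 7, directed=True)
        G = nx.relabel_nodes(G, {i: f"v{i}" for i in range(10)})
        G.remove_edges_from(nx.selfloop_edges(G))
        net = InteractionNetwork(G)
        seeds = sorted(rng.choice(sorted(G.nodes), size=4, replace=False))
        k = pair_counts(net, seed_pair_universe(net, seeds))
        g, _ = net.global_pair_counts()
        assert all(k[pair] <= g[pair] for pair in k)


class TestPairProbability:
    def test_zero_successes_is_certain(self):
        assert node_pair_probability(0, 4, 100, 10) == 1.0

    def test_exhaustive_draw_is_certain(self):
        assert node_pair_probability(3, 4, 10, 10) == pytest.approx(
            oracle_hypergeom_tail(3, 10, 4, 10))
        assert node_pair_probability(4, 4, 10, 10) == 1.0

    @pytest.mark.parametrize("k,M,n,N", [
        (3, 10, 4, 5), (1, 20, 3, 6), (2, 15, 5, 5), (5, 30, 10, 12),
    ])
    def test_matches_combinatorial_sum(self, k, M, n, N):
        assert node_pair_probability(k, n, M, N) == pytest.approx(
            oracle_hypergeom_tail(k, M, n, N), rel=1e-12)

    def test_p_decreases_in_k(self):
        ps = [node_pair_probability(k, 8, 100, 20) for k in range(1, 6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            node_pair_probability(5, 4, 100, 10)


class TestNetworkMethod:
    def test_planted_hub_funnel_is_reported(self):
        # funnel genes route through hub h in both directions; a background
        # cycle supplies plenty of connected pairs not involving the seeds
        funnel = [f"f{i}" for i in range(6)]
        edges = [(f, "h") for f in funnel] + [("h", f) for f in funnel]
        edges += [(f"b{i}", f"b{(i + 1) % 12}") for i in range(12)]
        net = net_from_edges(edges, targets={"h": ("drugX",)})
        z = {f: 3.0 for f in funnel}
        z.update({"h": 0.0})
        z.update({f"b{i}": 0.0 for i in range(12)})
        res = run_network_method(profile(z), net)
        assert any(r.target == "h" and "drugX" in r.drugs for r in res)
        top = [r for r in res if r.target == "h"][0]
        assert top.score == pytest.approx(-math.log10(top.p))

    def test_null_profile_reports_nothing(self):
        net = net_from_edges([("a", "b"), ("b", "c")], targets={"b": ("d",)})
        assert run_network_method(profile({"a": 0.0, "b": 0.0, "c": 0.0}), net) == []

    def test_single_seed_skips_analysis(self):
        net = net_from_edges([("a", "b"), ("b", "c")], targets={"b": ("d",)})
        assert run_network_method(profile({"a": 5.0, "b": 0.0, "c": 0.0}), net) == []
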