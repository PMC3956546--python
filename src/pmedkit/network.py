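"""Network Target Activity: drug-target inference from shortest-path topology.

From a tumor profile a seed set K of strongly over-expressed network
nodes is selected (all z >= 2, or the top-200 over-expressed).  The
directed shortest-path network S is the union of every shortest directed
path between ordered seed pairs, traversing non-seed nodes as needed.
For each node pair (i, j) the statistic counts how many seed pairs are
connected through both i and j (K_ij) and how many connected pairs in
the whole network are (N_ij).  The probability of observing K_ij or
more, when the seed pairs were a size-matched draw from all connected
pairs, is the hypergeometric upper tail; a small p marks (i, j) as a
topological funnel for the tumor's over-expressed program.  Node pairs
containing a known drug target with p below the reporting threshold
implicate that target's drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .crossmap import ZProfile

METHOD_NETWORK = "network-activity"

Pair = frozenset  # unordered node pair {i, j}


@dataclass
class InteractionNetwork:
    """Directed interaction graph plus a node -> drugs target map."""

    graph: nx.DiGraph
    target_drugs: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network contains self-loops: {loops[:3]}")
        self._apsp: dict | None = None
        self._global_counts: dict[bool, dict] = {}
        self._global_total: int | None = None

    # --- cached whole-network quantities -------------------------------
    def apsp(self) -> dict[str, dict[str, int]]:
        if self._apsp is None:
            self._apsp = {s: d for s, d in nx.all_pairs_shortest_path_length(self.graph)}
        return self._apsp

    def global_pair_counts(self, adjacent: bool = False) -> tuple[dict[Pair, int], int]:
        """(N_ij table over all connected ordered pairs, number of such pairs)."""
        if adjacent not in self._global_counts:
            dist = self.apsp()
            universe = [(s, t) for s, dt in dist.items() for t in dt if s != t]
            self._global_counts[adjacent] = pair_counts(self, universe, adjacent)
            self._global_total = len(universe)
        return self._global_counts[adjacent], self._global_total


@dataclass
class SeedSet:
    nodes: tuple[str, ...]
    mode: str

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class NodePairStat:
    pair: tuple[str, str]
    k_ij: int
    n_ij: int
    seed_pair_total: int
    global_pair_total: int
    p: float


@dataclass
class TargetActivityResult:
    target: str
    p: float
    drugs: tuple[str, ...]
    best_pair: tuple[str, str]
    score: float | None = None
    genes: list = field(default_factory=list)

    method = METHOD_NETWORK
    verdict = "indicated"


def select_seed(zp: ZProfile, net: InteractionNetwork,
                mode: Literal["threshold", "top200"] = "threshold",
                z_threshold: float = 2.0, top_n: int = 200) -> SeedSet:
    """Seed nodes: all z >= threshold, or the top-n over-expressed.

    Ties at the top-n boundary break by higher z then lexicographic id,
    so selection is deterministic.  The result is intersected with the
    network's node set.
    """
    z = zp.values
    if mode == "threshold":
        chosen = list(z.index[z >= z_threshold])
    elif mode == "top200":
        order = sorted(z.items(), key=lambda kv: (-kv[1], kv[0]))
        chosen = [ident for ident, _ in order[:top_n]]
    else:
        raise ValueError(f"unknown seed mode {mode!r}")
    nodes = tuple(sorted(set(chosen) & set(net.graph.nodes)))
    return SeedSet(nodes, mode)


def build_shortest_path_network(net: InteractionNetwork, seeds: Sequence[str]) -> nx.DiGraph:
    """Union of all shortest directed paths between distinct seed pairs.

    An edge (u, v) lies on some shortest s->t path iff
    d(s, u) + 1 + d(v, t) = d(s, t); unreachable pairs contribute nothing.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed nodes")
    G = net.graph
    fwd = {s: nx.single_source_shortest_path_length(G, s) for s in seeds}
    rev = G.reverse(copy=False)
    bwd = {t: nx.single_source_shortest_path_length(rev, t) for t in seeds}
    S = nx.DiGraph()
    for s in seeds:
        for t in seeds:
            if s == t or t not in fwd[s]:
                continue
            d = fwd[s][t]
            S.add_node(s)
            S.add_node(t)
            for u, v in G.edges:
                du = fwd[s].get(u)
                dv = bwd[t].get(v)
                if du is not None and dv is not None and du + 1 + dv == d:
                    S.add_edge(u, v)
    return S


def _on_path_nodes(G: nx.DiGraph, fwd_s: Mapping[str, int],
                   bwd_t: Mapping[str, int], d: int) -> list[str]:
    return [v for v, dv in fwd_s.items() if bwd_t.get(v, math.inf) + dv == d]


def pair_counts(net: InteractionNetwork,
                universe: Sequence[tuple[str, str]],
                adjacent: bool = False) -> dict[Pair, int]:
    """For each node pair {i, j}: number of universe pairs (s, t) with some
    shortest s->t path traversing both i and j (in either order along the path).

    Membership test uses distances: i and j lie on one common shortest
    path iff d(s,i) + d(i,j) + d(j,t) = d(s,t) for one of the two orders.
    With ``adjacent=True`` only pairs consecutive along a path (an edge
    of the shortest-path network) are counted — the restricted variant
    for sensitivity analysis.
    """
    dist = net.apsp()
    counts: dict[Pair, int] = {}
    for s, t in universe:
        dt = dist[s].get(t)
        if s == t or dt is None:
            continue
        ds = dist[s]
        bt = {v: dist[v].get(t) for v in ds}
        on_path = [v for v in ds if bt[v] is not None and ds[v] + bt[v] == dt]
        for i, j in combinations(sorted(on_path), 2):
            dij = dist[i].get(j)
            dji = dist[j].get(i)
            if adjacent:
                ok = (dij == 1 and ds[i] + 1 + bt[j] == dt) or \
                     (dji == 1 and ds[j] + 1 + bt[i] == dt)
            else:
                ok = (dij is not None and ds[i] + dij + bt[j] == dt) or \
                     (dji is not None and ds[j] + dji + bt[i] == dt)
            if ok:
                key = Pair((i, j))
                counts[key] = counts.get(key, 0) + 1
    return counts


def seed_pair_universe(net: InteractionNetwork, seeds: Sequence[str]) -> list[tuple[str, str]]:
    """Ordered seed pairs connected in the global network."""
    dist = net.apsp()
    return [(s, t) for s in seeds for t in seeds
            if s != t and t in dist.get(s, {})]


def node_pair_probability(k_ij: int, n_ij: int,
                          global_pair_total: int, seed_pair_total: int) -> float:
    """Hypergeometric upper tail P(X >= K_ij).

    Drawing ``seed_pair_total`` pairs from a population of
    ``global_pair_total`` connected pairs of which ``n_ij`` pass through
    both i and j, the probability of at least ``k_ij`` successes.
    """
    if k_ij > seed_pair_total or n_ij > global_pair_total or k_ij > n_ij:
        raise ValueError("inconsistent counts")
    if k_ij <= 0:
        return 1.0
    if global_pair_total <= 0 or seed_pair_total <= 0 or n_ij <= 0:
        return 1.0
    p = float(sps.hypergeom.sf(k_ij - 1, global_pair_total, n_ij, seed_pair_total))
    return min(max(p, float(np.finfo(float).tiny)), 1.0)


def run_network_method(zp: ZProfile, net: InteractionNetwork,
                       mode: Literal["threshold", "top200"] = "threshold",
                       alpha: float = 0.05,
                       z_threshold: float = 2.0,
                       top_n: int = 200,
                       adjacent: bool = False) -> list[TargetActivityResult]:
    """Significant node pairs mapped to the drug targets they contain.

    Per drug target, the best (smallest) p over node pairs involving it;
    targets with p < alpha are reported with their drugs and -log10(p).
    """
    seeds = select_seed(zp, net, mode, z_threshold, top_n)
    if len(seeds) < 2:
        return []
    global_counts, global_total = net.global_pair_counts(adjacent)
    seed_pairs = seed_pair_universe(net, seeds.nodes)
    if not seed_pairs:
        return []
    k_counts = pair_counts(net, seed_pairs, adjacent)
    best: dict[str, tuple[float, tuple[str, str]]] = {}
    for pair, k_ij in k_counts.items():
        n_ij = global_counts.get(pair, 0)
        p = node_pair_probability(k_ij, max(n_ij, k_ij), global_total, len(seed_pairs))
        for node in pair:
            if node in net.target_drugs:
                if node not in best or p < best[node][0]:
                    best[node] = (p, tuple(sorted(pair)))
    results = []
    for target, (p, pair) in sorted(best.items()):
        if p < alpha:
            results.append(TargetActivityResult(
                target=target, p=p, drugs=tuple(net.target_drugs[target]),
                best_pair=pair, score=-math.log10(p), genes=[target]))
    return sorted(results, key=lambda r: (r.p, r.target))


def read_network(edges_path, targets_path=None) -> InteractionNetwork:
    """Edge-list TSV (source, target, interaction) + optional (node, drug) map."""
    edges = pd.read_csv(edges_path, sep="\t")
    G = nx.DiGraph()
    for r in edges.itertuples():
        G.add_edge(str(r.source), str(r.target),
                   interaction=getattr(r, "interaction", ""))
    target_drugs: dict[str, tuple[str, ...]] = {}
    if targets_path is not None:
        tdf = pd.read_csv(targets_path, sep="\t")
        for node, grp in tdf.groupby("node", sort=True):
            target_drugs[str(node)] = tuple(sorted(set(map(str, grp["drug"]))))
    return InteractionNetwork(G, target_drugs)


def write_network(net: InteractionNetwork, edges_path, targets_path=None) -> None:
    rows = [{"source": u, "target": v,
             "interaction": d.get("interaction", "")}
            for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(rows).to_csv(edges_path, sep="\t", index=False)
    if targets_path is not None:
        trows = [{"node": node, "drug": drug}
                 for node, drugs in sorted(net.target_drugs.items())
                 for drug in drugs]
        pd.DataFrame(trows).to_csv(targets_path, sep="\t", index=False)
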