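"""Brute-force reference implementations for tiny graphs.

These oracles recompute every score from first principles — shortest paths
by exhaustive simple-path enumeration, clustering by direct neighbor-pair
counting, deletion scores by literally rebuilding the deleted graph — and
share no code with the igraph-backed fast paths in :mod:`netprio.scoring`.
They are exponential in graph size and intended for graphs of at most a
dozen nodes, where they serve as the independent side of the dual-route
equivalence tests.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from .network import InteractionNetwork
from .scoring import oracle_all_pairs


def _adjacency(network: InteractionNetwork) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {v: set() for v in network.nodes}
    for u, v in network.graph.edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def _all_simple_paths(adj, s, t):
    """Every simple path from s to t, by depth-first enumeration."""
    stack = [(s, [s], {s})]
    while stack:
        node, path, seen = stack.pop()
        if node == t:
            yield path
            continue
        for w in adj[node]:
            if w not in seen:
                stack.append((w, path + [w], seen | {w}))


def oracle_clustering(network: InteractionNetwork) -> dict[str, float]:
    """Local clustering: closed neighbor pairs over possible pairs."""
    adj = _adjacency(network)
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        closed = sum(1 for a, b in combinations(sorted(nbrs), 2) if b in adj[a])
        out[v] = closed / (k * (k - 1) / 2)
    return out


def oracle_betweenness(network: InteractionNetwork) -> dict[str, float]:
    """Pair-normalized betweenness from exhaustive shortest-path listing."""
    adj = _adjacency(network)
    nodes = network.nodes
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(_all_simple_paths(adj, s, t))
        if not paths:
            continue
        shortest_len = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == shortest_len]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            score[v] += through / len(shortest)
    if n >= 3:
        norm = (n - 1) * (n - 2) / 2.0
        score = {v: x / norm for v, x in score.items()}
    return score


def oracle_closeness(network: InteractionNetwork) -> dict[str, float]:
    """Normalized harmonic closeness from the BFS distance matrix."""
    dist, nodes = oracle_all_pairs(network)
    n = len(nodes)
    out = {}
    for i, v in enumerate(nodes):
        if n < 2:
            out[v] = 0.0
            continue
        total = sum(
            1.0 / dist[i, j]
            for j in range(n)
            if j != i and np.isfinite(dist[i, j])
        )
        out[v] = total / (n - 1)
    return out


def oracle_centrality_index(network: InteractionNetwork) -> float:
    """Mean over nodes of (clustering + betweenness + closeness) / 3."""
    if len(network.nodes) <= 1:
        return 0.0
    cc = oracle_clustering(network)
    bet = oracle_betweenness(network)
    clo = oracle_closeness(network)
    return float(
        np.mean([(cc[v] + bet[v] + clo[v]) / 3.0 for v in network.nodes])
    )


def _delete(network: InteractionNetwork, v: str) -> InteractionNetwork:
    g = network.graph.copy()
    g.remove_node(v)
    return InteractionNetwork(graph=g, metadata=dict(network.metadata))


def oracle_perturbation(network: InteractionNetwork) -> dict[str, float]:
    """|C(G) - C(G minus v)| by full recomputation per deletion."""
    base = oracle_centrality_index(network)
    return {
        v: abs(base - oracle_centrality_index(_delete(network, v)))
        for v in network.nodes
    }


def oracle_disruption(
    network: InteractionNetwork,
) -> dict[str, tuple[float, int]]:
    """Mean path-length increase and severed-pair count per deletion."""
    dist, nodes = oracle_all_pairs(network)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    out = {}
    for v in nodes:
        sub = _delete(network, v)
        d_after, remaining = oracle_all_pairs(sub)
        jdx = {w: j for j, w in enumerate(remaining)}
        increases = []
        severed = 0
        for u, w in combinations(remaining, 2):
            before = dist[idx[u], idx[w]]
            if not np.isfinite(before):
                continue
            after = d_after[jdx[u], jdx[w]]
            if not np.isfinite(after):
                severed += 1
                after = float(n)
            increases.append(after - before)
        out[v] = (float(np.mean(increases)) if increases else 0.0, severed)
    return out


def articulation_points(network: InteractionNetwork) -> set[str]:
    """Cut vertices, via the standard finder (cross-check for severed > 0)."""
    return set(nx.articulation_points(network.graph)) if network.nodes else set()
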