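"""Shared fixtures and graph-building helpers."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from netprio.network import InteractionNetwork


def make_network(edges, nodes=()) -> InteractionNetwork:
    """Build an InteractionNetwork from an edge list (confidence 0.9)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, confidence=0.9)
    return InteractionNetwork(graph=g)


def random_small_network(rng: np.random.Generator) -> InteractionNetwork:
    """A random graph on 2–8 nodes with random edge probability."""
    n = int(rng.integers(2, 9))
    p = float(rng.uniform(0.1, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    for u, v in g.edges:
        g.edges[u, v]["confidence"] = 0.9
    return InteractionNetwork(graph=g)


@pytest.fixture
def k3() -> InteractionNetwork:
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def five_cycle() -> InteractionNetwork:
    return make_network([(f"C{i}", f"C{(i + 1) % 5}") for i in range(5)])


@pytest.fixture
def path_abc() -> InteractionNetwork:
    return make_network([("A", "B"), ("B", "C")])
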