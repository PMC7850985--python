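"""Centralities and deletion-based scores against closed forms and oracles."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from netprio.oracles import (
    articulation_points,
    oracle_betweenness,
    oracle_centrality_index,
    oracle_closeness,
    oracle_disruption,
    oracle_perturbation,
)
from netprio.scoring import (
    compute_centralities,
    disruption_scores,
    network_centrality_index,
    oracle_all_pairs,
    perturbation_scores,
    score_nodes,
)

from conftest import make_network, random_small_network

TOL = 1e-9


class TestClosedForms:
    def test_triangle_symmetry(self, k3):
        c = compute_centralities(k3)
        assert (c["degree"] == 2).all()
        assert c["clustering"].eq(1.0).all()
        assert c["betweenness"].eq(0.0).all()
        assert c["closeness"].eq(1.0).all()
        assert network_centrality_index(k3) == pytest.approx(2 / 3)

    def test_star_center_and_leaf(self):
        star = make_network([("HUB", f"L{i}") for i in range(4)])
        c = compute_centralities(star)
        assert c.loc["HUB", "betweenness"] == pytest.approx(1.0)
        assert c.loc["HUB", "clustering"] == 0.0
        # leaf harmonic closeness: (1 + 3 * 1/2) / 4
        assert c.loc["L0", "closeness"] == pytest.approx(0.625)

    def test_edgeless_graph_index_zero(self):
        net = make_network([], nodes=[f"N{i}" for i in range(6)])
        assert network_centrality_index(net) == 0.0

    def test_single_node_index_zero(self):
        assert network_centrality_index(make_network([], nodes=["A"])) == 0.0

    def test_k5_perturbation_symmetric(self):
        k5 = make_network([(a, b) for a, b in combinations("ABCDE", 2)])
        p = perturbation_scores(k5)
        assert len(set(round(x, 12) for x in p.values())) == 1

    def test_path_perturbation_matches_definition(self, path_abc):
        p = perturbation_scores(path_abc)
        base = network_centrality_index(path_abc)
        # deleting B leaves A and C disconnected
        after = network_centrality_index(make_network([], nodes=["A", "C"]))
        assert p["B"] == pytest.approx(abs(base - after), abs=TOL)
        assert p == pytest.approx(oracle_perturbation(path_abc), abs=TOL)

    def test_five_cycle_disruption_one_sixth(self, five_cycle):
        d = disruption_scores(five_cycle)
        for score, severed in d.values():
            assert score == pytest.approx(1 / 6, abs=TOL)
            assert severed == 0

    def test_path_cut_vertex_penalty(self, path_abc):
        d = disruption_scores(path_abc)
        # deleting B severs (A, C): penalty 3 - 2 = 1
        assert d["B"] == (pytest.approx(1.0), 1)
        assert d["A"] == (pytest.approx(0.0), 0)

    def test_leaf_law(self):
        net = make_network(
            [("A", "B"), ("B", "C"), ("C", "A"), ("C", "LEAF")]
        )
        score, severed = disruption_scores(net)["LEAF"]
        assert score == 0.0 and severed == 0

    def test_preconditions(self):
        one = make_network([], nodes=["A"])
        with pytest.raises(ValueError):
            perturbation_scores(one)
        with pytest.raises(ValueError):
            disruption_scores(make_network([("A", "B")]))


class TestOracleEquivalence:
    """Fast igraph paths agree with brute-force recomputation."""

    @pytest.mark.parametrize("seed", range(30))
    def test_random_graphs_match_oracles(self, seed):
        rng = np.random.default_rng(1000 + seed)
        net = random_small_network(rng)
        c = compute_centralities(net)
        bet = oracle_betweenness(net)
        clo = oracle_closeness(net)
        for v in net.nodes:
            assert c.loc[v, "betweenness"] == pytest.approx(bet[v], abs=TOL)
            assert c.loc[v, "closeness"] == pytest.approx(clo[v], abs=TOL)
        assert network_centrality_index(net) == pytest.approx(
            oracle_centrality_index(net), abs=TOL
        )
        if len(net.nodes) >= 3:
            p = perturbation_scores(net)
            po = oracle_perturbation(net)
            d = disruption_scores(net)
            do = oracle_disruption(net)
            for v in net.nodes:
                assert p[v] == pytest.approx(po[v], abs=TOL)
                assert d[v][0] == pytest.approx(do[v][0], abs=TOL)
                assert d[v][1] == do[v][1]

    @pytest.mark.parametrize("seed", range(25))
    def test_severed_pairs_iff_articulation_point(self, seed):
        rng = np.random.default_rng(2000 + seed)
        net = random_small_network(rng)
        if len(net.nodes) < 3:
            return
        cuts = articulation_points(net)
        for v, (_, severed) in disruption_scores(net).items():
            assert (severed > 0) == (v in cuts)


class TestAllPairsOracle:
    def test_k4_all_adjacent(self):
        k4 = make_network([(a, b) for a, b in combinations("ABCD", 2)])
        dist, _ = oracle_all_pairs(k4)
        off = dist[~np.eye(4, dtype=bool)]
        assert (off == 1).all()

    def test_disconnected_components_infinite(self):
        net = make_network([("A", "B"), ("C", "D")])
        dist, nodes = oracle_all_pairs(net)
        i, j = nodes.index("A"), nodes.index("C")
        assert np.isinf(dist[i, j])

    def test_five_cycle_wraps(self, five_cycle):
        dist, nodes = oracle_all_pairs(five_cycle)
        idx = {v: i for i, v in enumerate(nodes)}
        assert dist[idx["C0"], idx["C2"]] == 2
        assert dist[idx["C0"], idx["C3"]] == 2  # wrapping through C4


class TestScaleInvariants:
    def test_isolated_node_leaves_disruption_unchanged(self, five_cycle):
        from netprio.network import InteractionNetwork

        base_d = disruption_scores(five_cycle)
        g = five_cycle.graph.copy()
        g.add_node("ISO")
        bigger = InteractionNetwork(graph=g)
        d = disruption_scores(bigger)
        for v in five_cycle.nodes:
            assert d[v][0] == pytest.approx(base_d[v][0], abs=TOL)
            assert d[v][1] == base_d[v][1]
        # perturbation rescales only through the 1/|V| normalization of the
        # index; it still matches the brute-force recomputation exactly
        p_big = perturbation_scores(bigger)
        assert p_big["C0"] == pytest.approx(oracle_perturbation(bigger)["C0"], abs=TOL)

    def test_score_table_columns_and_bounds(self):
        rng = np.random.default_rng(7)
        net = random_small_network(rng)
        if len(net.nodes) < 3:
            net = make_network([("A", "B"), ("B", "C"), ("C", "D")])
        table = score_nodes(net)
        n = len(net.nodes)
        assert (table["degree"] <= n - 1).all()
        for col in ("clustering", "betweenness", "closeness"):
            assert table[col].between(0.0, 1.0).all()
        assert (table["perturbation"] >= 0).all()
        assert (table["disruption"] >= 0).all()
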