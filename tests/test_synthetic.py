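"""Synthetic-input generators: determinism, planted structure, prevalences."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

from netprio.errors import ConfigurationError
from netprio.synthetic import (
    GeneratorSpec,
    generate_annotations,
    generate_identifications,
    generate_network,
    table1_fixture,
    table2_fixture,
)


class TestGenerateNetwork:
    def test_er_extremes(self):
        empty = generate_network(
            GeneratorSpec(n_nodes=10, topology="erdos_renyi", edge_probability=0.0)
        )
        assert empty.number_of_edges() == 0 and empty.number_of_nodes() == 10
        full = generate_network(
            GeneratorSpec(n_nodes=10, topology="erdos_renyi", edge_probability=1.0)
        )
        assert full.number_of_edges() == 45

    def test_planted_hub_degree(self):
        net = generate_network(
            GeneratorSpec(
                n_nodes=200, attachment_edges=2, planted_hub=0.5, seed=11
            )
        )
        hub = net.metadata["planted_hub"]
        assert net.graph.degree[hub] >= math.ceil(0.5 * 199)

    def test_seed_determinism_byte_identical(self, tmp_path):
        from netprio.network import write_edges

        spec = GeneratorSpec(n_nodes=80, attachment_edges=2, planted_hub=0.3, seed=4)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_edges(generate_network(spec), a)
        write_edges(generate_network(spec), b)
        assert a.read_bytes() == b.read_bytes()

    def test_confidences_in_string_medium_band(self):
        net = generate_network(GeneratorSpec(n_nodes=50, attachment_edges=2, seed=2))
        confs = [net.confidence(u, v) for u, v in net.graph.edges]
        assert all(0.4 <= c <= 1.0 for c in confs)

    def test_heavy_tail_beats_er_max_degree(self):
        pa_max, er_max = [], []
        for seed in range(10):
            pa = generate_network(
                GeneratorSpec(n_nodes=150, attachment_edges=2, seed=seed)
            )
            m = pa.number_of_edges()
            er = generate_network(
                GeneratorSpec(
                    n_nodes=150,
                    topology="erdos_renyi",
                    edge_probability=2 * m / (150 * 149),
                    seed=seed,
                )
            )
            pa_max.append(max(d for _, d in pa.graph.degree))
            er_max.append(max(d for _, d in er.graph.degree))
        assert np.median(pa_max) > np.median(er_max)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorSpec(n_nodes=10, topology="erdos_renyi")  # p missing
        with pytest.raises(ConfigurationError):
            GeneratorSpec(n_nodes=5, attachment_edges=5)
        with pytest.raises(ConfigurationError):
            GeneratorSpec(n_nodes=10, attachment_edges=2, planted_hub=1.5)
        with pytest.raises(ConfigurationError):
            GeneratorSpec(n_nodes=10, topology="smallworld")

    def test_ring_lattice_regular(self):
        net = generate_network(
            GeneratorSpec(n_nodes=12, topology="ring_lattice", ring_neighbors=4)
        )
        assert all(d == 4 for _, d in net.graph.degree)


class TestGenerateIdentifications:
    @pytest.mark.parametrize("frac,expect", [(1.0, 100), (0.0, 0)])
    def test_extreme_fractions(self, frac, expect):
        from netprio.evidence import filter_identifications

        records, truth = generate_identifications(100, frac, seed=1)
        kept, _ = filter_identifications(records)
        assert truth == expect and len(kept) == expect

    def test_study_scale_planting(self):
        from netprio.evidence import filter_identifications

        records, truth = generate_identifications(672, 347 / 672, seed=5)
        assert truth == 347
        kept, removed = filter_identifications(records)
        assert len(kept) == 347 and len(removed) == 325

    def test_determinism(self):
        a, _ = generate_identifications(50, 0.4, seed=9)
        b, _ = generate_identifications(50, 0.4, seed=9)
        assert a == b


class TestGenerateAnnotations:
    @pytest.mark.parametrize("prev,expect", [(1.0, True), (0.0, False)])
    def test_extreme_prevalences(self, prev, expect):
        table = generate_annotations(["A", "B", "C"], {"c": prev}, seed=1)
        assert all(table.lookup(s, "c") is expect for s in "ABC")

    def test_empirical_frequency_within_3_se(self):
        n = 10_000
        symbols = [f"S{i}" for i in range(n)]
        table = generate_annotations(symbols, {"c": 0.3}, seed=3)
        freq = sum(table.lookup(s, "c") for s in symbols) / n
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(freq - 0.3) <= 3 * se


class TestFixtures:
    def test_sizes_and_spot_values(self):
        hub, pert, disr, expected = table1_fixture()
        assert len(hub) == len(pert) == len(disr) == len(expected) == 20
        assert (hub["HSPA5"], pert["HSPA5"], disr["HSPA5"]) == (12, 13, 6)
        assert expected.loc["HSPA5", "average_rank"] == 10.33
        assert expected.loc["HSPA5", "cumulative_rank"] == 7
        table2 = table2_fixture()
        assert len(table2.flags) == 20
        gapdh = table2.flags["GAPDH"]
        assert gapdh == {
            "prostate_expression": True,
            "prostate_cancer": True,
            "prostate_cancer_metastasis": False,
            "apoptosis": True,
        }


def test_end_to_end_planted_hub_recovered_single_seed():
    """One seeded run of the full scoring+ranking chain finds the hub."""
    from netprio.ranking import rank_scores, shortlist_top_fraction
    from netprio.scoring import score_nodes

    net = generate_network(
        GeneratorSpec(n_nodes=120, attachment_edges=2, planted_hub=0.5, seed=11)
    )
    table = rank_scores(score_nodes(net))
    hub = net.metadata["planted_hub"]
    assert table.loc[hub, "cumulative_rank"] == 1
    assert hub in shortlist_top_fraction(table, 0.05)
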