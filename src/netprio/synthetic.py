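"""Seeded synthetic inputs and embedded reference fixtures.

The real study inputs — a mass-spectrometry identification table and a
STRING interaction download — are replaced here by generators that emulate
their structure:

* :func:`generate_network` — a PPI stand-in with a heavy-tailed degree
  distribution (preferential attachment by default, mimicking real
  interactomes; Erdős–Rényi and ring-lattice retained for symmetric and
  degenerate oracle cases), optionally with one *planted hub* wired to a
  chosen fraction of all other nodes;
* :func:`generate_identifications` — an evidence table in which a controlled
  fraction of records passes the default thresholds, with the planted ground
  truth returned alongside;
* :func:`generate_annotations` — boolean annotation tables with stated
  per-criterion prevalences.

Every generator is fully determined by its seed.  The module also embeds,
verbatim, the published 20-protein rank table and annotation table used by
the acceptance tests (:func:`table1_fixture`, :func:`table2_fixture`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .evidence import ProteinRecord
from .network import InteractionNetwork
from .screen import AnnotationTable

TOPOLOGIES = ("preferential_attachment", "erdos_renyi", "ring_lattice")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic interaction network.

    ``attachment_edges`` (m) applies to preferential attachment,
    ``edge_probability`` (p) to Erdős–Rényi, ``ring_neighbors`` (k) to the
    ring lattice.  ``planted_hub`` connects the first node to that fraction
    of all other nodes, wired after the base topology.
    """

    n_nodes: int
    topology: str = "preferential_attachment"
    attachment_edges: int | None = None
    edge_probability: float | None = None
    ring_neighbors: int | None = None
    planted_hub: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ConfigurationError(f"n_nodes must be >= 1, got {self.n_nodes}")
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(
                f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}"
            )
        if self.topology == "preferential_attachment":
            m = self.attachment_edges
            if m is None or not 1 <= m < self.n_nodes:
                raise ConfigurationError(
                    "preferential attachment needs 1 <= attachment_edges < n_nodes"
                )
        elif self.topology == "erdos_renyi":
            p = self.edge_probability
            if p is None or not 0.0 <= p <= 1.0:
                raise ConfigurationError("erdos_renyi needs edge_probability in [0,1]")
        else:
            k = self.ring_neighbors
            if k is None or k < 2 or k >= self.n_nodes or k % 2:
                raise ConfigurationError(
                    "ring_lattice needs even ring_neighbors in [2, n_nodes)"
                )
        if self.planted_hub is not None and not 0.0 < self.planted_hub <= 1.0:
            raise ConfigurationError("planted_hub must be in (0, 1]")


def gene_symbols(n: int) -> list[str]:
    """Synthetic gene symbols G0001, G0002, ... (width grows with n)."""
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(spec: GeneratorSpec) -> InteractionNetwork:
    """Build a seeded synthetic interaction network per ``spec``.

    Edge confidences are sampled uniformly on [0.4, 1.0] and quantized to 3
    decimals (the on-disk precision, so files round-trip exactly).  The
    planted hub, when requested, is the first node and is wired last.
    """
    n = spec.n_nodes
    if spec.topology == "preferential_attachment":
        base = nx.barabasi_albert_graph(n, spec.attachment_edges, seed=spec.seed)
    elif spec.topology == "erdos_renyi":
        base = nx.gnp_random_graph(n, spec.edge_probability, seed=spec.seed)
    else:
        base = nx.watts_strogatz_graph(n, spec.ring_neighbors, 0.0, seed=spec.seed)
    symbols = gene_symbols(n)
    g = nx.relabel_nodes(base, dict(enumerate(symbols)), copy=True)

    rng = np.random.default_rng(spec.seed)
    if spec.planted_hub is not None and n > 1:
        hub = symbols[0]
        others = symbols[1:]
        n_links = math.ceil(spec.planted_hub * (n - 1))
        targets = rng.choice(len(others), size=n_links, replace=False)
        for t in targets:
            g.add_edge(hub, others[t])
    for u, v in g.edges:
        g.edges[u, v]["confidence"] = round(float(rng.uniform(0.4, 1.0)), 3)
    return InteractionNetwork(
        graph=g,
        metadata={
            "source": f"synthetic:{spec.topology}",
            "seed": spec.seed,
            "planted_hub": symbols[0] if spec.planted_hub else None,
            "min_confidence": 0.4,
        },
    )


def generate_identifications(
    n: int,
    pass_fraction: float,
    seed: int,
    symbols: list[str] | None = None,
) -> tuple[list[ProteinRecord], int]:
    """Evidence table with exactly ``round(pass_fraction·n)`` passing records.

    Passing records satisfy the default thresholds (≥2 unique peptides and
    ≥2 PSMs); failing records violate at least one, split between the
    too-few-peptides and too-few-PSMs failure modes.  Returns the records
    (in shuffled order) and the planted pass count as ground truth.
    """
    if not 0.0 <= pass_fraction <= 1.0:
        raise ConfigurationError(f"pass_fraction must be in [0,1], got {pass_fraction}")
    rng = np.random.default_rng(seed)
    syms = symbols if symbols is not None else gene_symbols(n)
    if len(syms) != n:
        raise ConfigurationError(f"need {n} symbols, got {len(syms)}")
    n_pass = round(pass_fraction * n)
    passing = np.zeros(n, dtype=bool)
    passing[rng.choice(n, size=n_pass, replace=False)] = True
    records: list[ProteinRecord] = []
    for i, sym in enumerate(syms):
        if passing[i]:
            up = int(rng.integers(2, 16))
            psms = int(rng.integers(max(2, up), 4 * up + 8))
        elif rng.random() < 0.5:
            up = int(rng.integers(0, 2))  # 0 or 1 unique peptides
            psms = int(rng.integers(1, 12)) if up else 0
        else:
            up = int(rng.integers(2, 16))
            psms = 1  # enough peptides but a single PSM overall
        records.append(
            ProteinRecord(
                accession=f"SYN{i + 1:05d}",
                gene_symbol=sym,
                unique_peptides=up,
                psms=psms,
                search_score=float(np.round(rng.gamma(2.0, 20.0), 2)),
            )
        )
    order = rng.permutation(n)
    return [records[i] for i in order], n_pass


def generate_annotations(
    symbols: list[str],
    prevalences: dict[str, float],
    seed: int,
) -> AnnotationTable:
    """Boolean annotations: independent draws at the stated prevalences."""
    for crit, p in prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"prevalence for {crit!r} must be in [0,1]")
    rng = np.random.default_rng(seed)
    criteria = list(prevalences)
    flags = {
        s: {c: bool(rng.random() < prevalences[c]) for c in criteria}
        for s in symbols
    }
    return AnnotationTable(
        criteria=criteria,
        flags=flags,
        provenance={c: "synthetic" for c in criteria},
    )


# --- embedded published-table fixtures -------------------------------------

#: protein -> (hub rank, perturbation rank, disruption rank, printed average,
#:            printed cumulative rank)
_TABLE1_ROWS: list[tuple[str, int, int, int, float, int]] = [
    ("GAPDH", 1, 1, 1, 1.00, 1),
    ("HSPA8", 2, 2, 3, 2.33, 2),
    ("HSP90AA1", 3, 3, 13, 6.33, 3),
    ("HSPA4", 4, 6, 9, 6.33, 3),
    ("ENO1", 6, 4, 16, 8.67, 4),
    ("TPI1", 7, 19, 2, 9.33, 5),
    ("VCP", 11, 12, 5, 9.33, 5),
    ("CCT2", 5, 10, 15, 10.00, 6),
    ("HSPA5", 12, 13, 6, 10.33, 7),
    ("LCN2", 6, 18, 8, 10.67, 8),
    ("EEF2", 18, 8, 7, 11.00, 9),
    ("ACTG1", 15, 9, 10, 11.33, 10),
    ("HSPD1", 8, 16, 12, 12.00, 11),
    ("PDIA6", 16, 7, 14, 12.33, 12),
    ("CCT8", 9, 11, 17, 12.33, 12),
    ("S100A7", 17, 20, 4, 13.67, 13),
    ("HSPA9", 13, 17, 11, 13.67, 13),
    ("LCN1", 19, 5, 19, 14.33, 14),
    ("HSP90AB1", 10, 15, 20, 15.00, 15),
    ("CCT5", 14, 14, 18, 15.33, 16),
]

#: Table 2 criteria in column order, with their provenance labels.
TABLE2_CRITERIA: dict[str, str] = {
    "prostate_expression": "protein atlas",
    "prostate_cancer": "DisGeNET C0376358",
    "prostate_cancer_metastasis": "DisGeNET C1282496",
    "apoptosis": "ApocanD/IPA",
}

#: protein -> (prostate expression, prostate cancer, metastasis, apoptosis)
_TABLE2_ROWS: list[tuple[str, bool, bool, bool, bool]] = [
    ("GAPDH", True, True, False, True),
    ("HSPA8", True, True, False, True),
    ("HSP90AA1", False, True, True, True),
    ("HSPA4", True, True, False, True),
    ("TPI1", True, False, False, False),
    ("ENO1", True, True, False, True),
    ("VCP", True, True, False, True),
    ("CCT2", True, True, False, True),
    ("HSPA5", True, True, True, True),
    ("LCN2", False, True, False, True),
    ("EEF2", True, True, False, True),
    ("ACTG1", True, True, False, False),
    ("HSPD1", True, True, False, True),
    ("PDIA6", True, False, False, False),
    ("CCT8", True, False, False, False),
    ("S100A7", False, True, False, True),
    ("HSPA9", True, True, False, True),
    ("LCN1", False, False, False, False),
    ("HSP90AB1", True, True, False, True),
    ("CCT5", True, False, False, True),
]


def table1_fixture() -> tuple[
    dict[str, int], dict[str, int], dict[str, int], pd.DataFrame
]:
    """The published 20-protein rank table, verbatim.

    Returns the three per-metric rank maps (hub, perturbation, disruption)
    plus a DataFrame of the printed expected values (columns
    ``average_rank`` and ``cumulative_rank``, indexed by protein).
    """
    hub = {r[0]: r[1] for r in _TABLE1_ROWS}
    pert = {r[0]: r[2] for r in _TABLE1_ROWS}
    disr = {r[0]: r[3] for r in _TABLE1_ROWS}
    expected = pd.DataFrame(
        {
            "average_rank": [r[4] for r in _TABLE1_ROWS],
            "cumulative_rank": [r[5] for r in _TABLE1_ROWS],
        },
        index=pd.Index([r[0] for r in _TABLE1_ROWS], name="protein"),
    )
    return hub, pert, disr, expected


def table2_fixture() -> AnnotationTable:
    """The published 20-protein annotation table, verbatim."""
    criteria = list(TABLE2_CRITERIA)
    flags = {
        row[0]: dict(zip(criteria, row[1:])) for row in _TABLE2_ROWS
    }
    return AnnotationTable(
        criteria=criteria, flags=flags, provenance=dict(TABLE2_CRITERIA)
    )
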