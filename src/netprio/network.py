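"""STRING-style edge lists and the undirected interaction network.

Edges come as ``protein1 protein2 combined_score`` rows where the combined
score is an integer confidence on the 0–1000 scale; it is normalized to
[0, 1] on input.  The network is an undirected simple graph: self-loops are
dropped, reciprocal duplicates (A–B and B–A) are merged keeping the maximum
confidence, and edges below the confidence cutoff are discarded.  Confidence
affects only edge inclusion — all topological scores downstream are
unweighted.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import networkx as nx

from .errors import EmptyNetworkError, RowParseError

logger = logging.getLogger("netprio")

#: STRING's "medium confidence" cutoff on the normalized scale.
DEFAULT_MIN_CONFIDENCE = 0.4


@dataclass
class InteractionNetwork:
    """Undirected simple graph with confidence-weighted edges.

    ``graph`` is a :class:`networkx.Graph` whose nodes are gene symbols and
    whose edges carry a ``confidence`` attribute in [0, 1].  ``metadata``
    records the source label and the confidence threshold applied, so every
    derived result carries its provenance.
    """

    graph: nx.Graph
    metadata: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        """Node identifiers in deterministic (lexicographic) order."""
        return sorted(self.graph.nodes)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def confidence(self, u: str, v: str) -> float:
        return float(self.graph.edges[u, v]["confidence"])


def _iter_rows(source: str | Path | TextIO):
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from enumerate(fh, start=1)
    else:
        yield from enumerate(source, start=1)


def read_string_edges(
    source: str | Path | TextIO,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    aliases: Mapping[str, str] | None = None,
    source_label: str = "string",
) -> InteractionNetwork:
    """Parse a STRING-style edge list into an :class:`InteractionNetwork`.

    Rows are whitespace- or tab-delimited ``protein1 protein2 combined_score``
    with the score an integer in 0–1000; a header row is recognized and
    skipped.  The normalized dialect written by :func:`write_edges` (real
    confidence in [0, 1]) is accepted too, so edge lists round-trip.
    ``aliases`` optionally maps raw identifiers to gene symbols.

    Raises :class:`RowParseError` listing malformed rows, and
    :class:`EmptyNetworkError` when no edge survives the confidence filter.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0,1], got {min_confidence}")
    best: dict[tuple[str, str], float] = {}
    bad: list[tuple[int, str]] = []
    n_self_loops = 0
    n_rows = 0
    for row_no, line in _iter_rows(source):
        parts = line.replace(",", "\t").split()
        if not parts:
            continue
        if len(parts) < 3:
            bad.append((row_no, f"expected 3 columns, got {len(parts)}"))
            continue
        a, b, raw = parts[0], parts[1], parts[2]
        if row_no == 1:
            try:
                float(raw)
            except ValueError:
                continue  # header
        n_rows += 1
        if "." in raw:  # normalized dialect: real confidence in [0,1]
            try:
                conf = float(raw)
            except ValueError:
                bad.append((row_no, f"malformed confidence {raw!r}"))
                continue
            if not 0.0 <= conf <= 1.0:
                bad.append((row_no, f"confidence {conf} outside [0,1]"))
                continue
        else:
            try:
                score = int(raw)
            except ValueError:
                bad.append((row_no, f"malformed combined_score {raw!r}"))
                continue
            if not 0 <= score <= 1000:
                bad.append((row_no, f"combined_score {score} outside 0–1000"))
                continue
            conf = score / 1000.0
        if aliases:
            a = aliases.get(a, a)
            b = aliases.get(b, b)
        if a == b:
            n_self_loops += 1
            continue
        key = (a, b) if a < b else (b, a)
        if conf > best.get(key, -1.0):
            best[key] = conf
    if bad:
        raise RowParseError("invalid edge rows", bad)
    if n_self_loops:
        logger.warning("dropped %d self-loop edge(s)", n_self_loops)

    g = nx.Graph()
    for (a, b), conf in best.items():
        if conf >= min_confidence:
            g.add_edge(a, b, confidence=conf)
    if g.number_of_edges() == 0:
        raise EmptyNetworkError(
            f"no edges at min_confidence={min_confidence} "
            f"({n_rows} input rows, {len(best)} distinct pairs)"
        )
    logger.info(
        "read %d edges on %d nodes (min_confidence=%.2f, %d rows)",
        g.number_of_edges(), g.number_of_nodes(), min_confidence, n_rows,
    )
    return InteractionNetwork(
        graph=g,
        metadata={"source": source_label, "min_confidence": min_confidence},
    )


def induce_subnetwork(
    network: InteractionNetwork,
    node_set: Iterable[str],
    include_missing: bool = True,
) -> InteractionNetwork:
    """Restrict the network to ``node_set``.

    Nodes of ``node_set`` absent from the edge list are kept as isolated
    nodes when ``include_missing`` is true (the default), so proteins with no
    known interactions still receive (worst) ranks downstream instead of
    vanishing from the ranked list.
    """
    wanted = set(node_set)
    if not wanted:
        raise ValueError("node_set is empty")
    sub = nx.Graph()
    present = wanted & set(network.graph.nodes)
    sub.add_nodes_from(present if not include_missing else wanted)
    for u, v, data in network.graph.edges(data=True):
        if u in wanted and v in wanted:
            sub.add_edge(u, v, **data)
    meta = dict(network.metadata)
    meta["induced_on"] = len(wanted)
    return InteractionNetwork(graph=sub, metadata=meta)


def write_edges(network: InteractionNetwork, path: str | Path) -> None:
    """Write the normalized edge list as ``node_a  node_b  confidence`` TSV.

    Confidence is printed as a 0–1 real with 3 decimals; endpoints are sorted
    within and across rows so output is byte-stable.
    """
    rows = sorted(
        (min(u, v), max(u, v), data["confidence"])
        for u, v, data in network.graph.edges(data=True)
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["node_a", "node_b", "confidence"])
        for a, b, conf in rows:
            writer.writerow([a, b, f"{conf:.3f}"])
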