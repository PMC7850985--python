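"""End-to-end orchestration: evidence filter → network → scores → ranks → screen."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .evidence import (
    EvidenceThresholds,
    ProteinRecord,
    add_bait,
    collapse_isoforms,
    filter_identifications,
    parse_identifications,
    write_identifications,
)
from .network import induce_subnetwork, read_string_edges, write_edges
from .ranking import rank_scores, shortlist_top_fraction, write_rank_table
from .scoring import score_nodes, write_scores
from .screen import CandidateReport, parse_annotations, screen_candidates, write_report

logger = logging.getLogger("netprio")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    identifications_path: str | Path,
    edges_path: str | Path,
    annotations_path: str | Path,
    output_dir: str | Path | None = None,
) -> CandidateReport:
    """Run the full prioritization chain and write every intermediate.

    Outputs in ``output_dir``: kept/removed identification TSVs, the induced
    edge list, the per-node score table, the rank table, the candidate
    report (text + TSV) and a run manifest (effective config, input
    checksums, versions).  On any stage failure the partially written
    outputs of this run are removed before the error propagates.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def target(name: str) -> Path:
        p = out / name
        written.append(p)
        return p

    try:
        thresholds = EvidenceThresholds(config.min_unique_peptides, config.min_psms)
        records = parse_identifications(identifications_path)
        kept, removed = filter_identifications(records, thresholds)
        kept = collapse_isoforms(kept)
        if config.bait_symbol:
            kept = add_bait(
                kept,
                ProteinRecord(
                    accession="BAIT",
                    gene_symbol=config.bait_symbol,
                    unique_peptides=0,
                    psms=0,
                ),
            )
        write_identifications(kept, target("identifications_kept.tsv"))
        write_identifications(removed, target("identifications_removed.tsv"))

        full = read_string_edges(edges_path, min_confidence=config.min_confidence)
        node_set = {r.gene_symbol for r in kept}
        network = induce_subnetwork(full, node_set)
        write_edges(network, target("network_edges.tsv"))

        scores = score_nodes(network)
        write_scores(scores, target("node_scores.tsv"))

        if not config.include_bait and config.bait_symbol:
            scores = scores.drop(index=config.bait_symbol, errors="ignore")
        ranks = rank_scores(scores)
        write_rank_table(ranks, target("rank_table.tsv"))

        shortlist = shortlist_top_fraction(ranks, config.fraction)
        annotations = parse_annotations(annotations_path)
        report = screen_candidates(
            shortlist,
            annotations,
            config.conjunction,
            cumulative_ranks=ranks["cumulative_rank"].to_dict(),
        )
        write_report(
            report, target("candidate_report.txt"), target("candidate_report.tsv")
        )

        manifest = {
            "config": {
                k: getattr(config, k) for k in config.__dataclass_fields__
            },
            "inputs": {
                "identifications": _sha256(identifications_path),
                "edges": _sha256(edges_path),
                "annotations": _sha256(annotations_path),
            },
            "counts": {
                "records_in": len(records),
                "records_kept": len(kept),
                "network_nodes": network.number_of_nodes(),
                "network_edges": network.number_of_edges(),
                "shortlist": len(shortlist),
                "final_candidates": len(report.final_candidates),
            },
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        target("manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        logger.info(
            "pipeline done: %d kept, shortlist %d, candidates %s",
            len(kept), len(shortlist), report.final_candidates,
        )
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
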