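"""Spectral-evidence filtering of protein identification tables.

A pull-down followed by LC-MS/MS yields a table of identified proteins with,
per protein, the number of unique peptides and the number of peptide-spectrum
matches (PSMs) supporting the identification.  Only proteins with enough
independent evidence are admitted to the interactome: the default thresholds
keep proteins identified with at least two unique peptides and at least two
PSMs.  The bait protein itself is typically depleted before MS and is added
back explicitly so the downstream network contains it.

The filter has two granularities:

* protein level (default) — thresholds applied to the per-protein totals,
  which is the granularity of typical published supplementary tables;
* peptide level (strict) — available when a per-peptide PSM table is
  supplied: a protein is kept when at least ``min_unique_peptides`` of its
  peptides each carry ``min_psms`` or more PSMs.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .errors import ConfigurationError, RowParseError

logger = logging.getLogger("netprio")

#: Default header names, matching common Proteome Discoverer exports.
DEFAULT_COLUMNS: dict[str, str] = {
    "accession": "Accession",
    "gene_symbol": "Gene Symbol",
    "unique_peptides": "# Unique Peptides",
    "psms": "# PSMs",
}

#: Optional column carrying the search-engine score; absent in many exports.
SCORE_COLUMN = "search_score"


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein with its spectral evidence counts.

    ``gene_symbol`` is the unique key used for all downstream network joins.
    ``psms >= unique_peptides`` is *not* required (one peptide may have many
    spectra), but a record claiming peptides with zero PSMs is contradictory
    and rejected.
    """

    accession: str
    gene_symbol: str
    unique_peptides: int
    psms: int
    search_score: float | None = None
    is_bait: bool = False

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError(f"empty gene symbol for accession {self.accession!r}")
        if self.unique_peptides < 0 or self.psms < 0:
            raise ValueError(
                f"negative evidence counts for {self.gene_symbol}: "
                f"unique_peptides={self.unique_peptides}, psms={self.psms}"
            )
        if self.unique_peptides >= 1 and self.psms < 1:
            raise ValueError(
                f"{self.gene_symbol}: {self.unique_peptides} unique peptide(s) "
                "but zero PSMs"
            )


@dataclass(frozen=True)
class EvidenceThresholds:
    """Minimum evidence for a protein to enter the interactome.

    ``min_psms`` is applied to the protein's total PSM count in the default
    protein-level mode, and per peptide in the strict mode.
    """

    min_unique_peptides: int = 2
    min_psms: int = 2

    def __post_init__(self) -> None:
        if self.min_unique_peptides < 1 or self.min_psms < 1:
            raise ConfigurationError(
                "evidence thresholds must be >= 1, got "
                f"min_unique_peptides={self.min_unique_peptides}, "
                f"min_psms={self.min_psms}"
            )


def _open_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def parse_identifications(
    source: str | Path | TextIO,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[ProteinRecord]:
    """Read a delimited identification table into :class:`ProteinRecord` rows.

    ``columns`` maps the logical fields (``accession``, ``gene_symbol``,
    ``unique_peptides``, ``psms``, optionally ``search_score``) to the header
    names actually present; unmapped fields fall back to
    :data:`DEFAULT_COLUMNS`.  The delimiter is sniffed from the header line
    (tab if present, else comma) unless given.

    Raises
    ------
    ConfigurationError
        if a mapped column is missing from the header.
    RowParseError
        listing every row whose counts could not be parsed; rows are never
        silently dropped.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    stream, owned = _open_text(source)
    try:
        first = stream.readline()
        if not first:
            raise ConfigurationError("identification table is empty (no header)")
        delim = delimiter or _sniff_delimiter(first)
        header = next(csv.reader(io.StringIO(first), delimiter=delim))
        index: dict[str, int] = {}
        for field in ("accession", "gene_symbol", "unique_peptides", "psms"):
            name = colmap[field]
            if name not in header:
                raise ConfigurationError(
                    f"column {name!r} (for {field}) not found in header {header}"
                )
            index[field] = header.index(name)
        score_name = colmap.get(SCORE_COLUMN)
        score_idx = header.index(score_name) if score_name in header else None

        records: list[ProteinRecord] = []
        bad: list[tuple[int, str]] = []
        for row_no, row in enumerate(csv.reader(stream, delimiter=delim), start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                up = int(row[index["unique_peptides"]])
                ps = int(row[index["psms"]])
            except (ValueError, IndexError) as exc:
                bad.append((row_no, f"unparseable count ({exc})"))
                continue
            score = None
            if score_idx is not None and score_idx < len(row) and row[score_idx].strip():
                try:
                    score = float(row[score_idx])
                except ValueError:
                    bad.append((row_no, "unparseable search score"))
                    continue
            try:
                records.append(
                    ProteinRecord(
                        accession=row[index["accession"]].strip(),
                        gene_symbol=row[index["gene_symbol"]].strip(),
                        unique_peptides=up,
                        psms=ps,
                        search_score=score,
                    )
                )
            except (ValueError, IndexError) as exc:
                bad.append((row_no, str(exc)))
        if bad:
            raise RowParseError("invalid identification rows", bad)
        return records
    finally:
        if owned:
            stream.close()


def filter_identifications(
    records: Sequence[ProteinRecord],
    thresholds: EvidenceThresholds = EvidenceThresholds(),
    peptide_psms: Mapping[str, Sequence[int]] | None = None,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition records into ``(kept, removed)`` under the thresholds.

    Default protein-level contract: keep when
    ``unique_peptides >= min_unique_peptides`` and ``psms >= min_psms``.

    When ``peptide_psms`` maps an accession to its per-peptide PSM counts the
    strict peptide-level rule applies to that record instead: keep when at
    least ``min_unique_peptides`` peptides each have ``>= min_psms`` PSMs.
    Records absent from the table fall back to the protein-level rule.

    The two output lists partition the input and preserve its order.
    """
    kept: list[ProteinRecord] = []
    removed: list[ProteinRecord] = []
    for rec in records:
        if peptide_psms is not None and rec.accession in peptide_psms:
            good = sum(
                1 for p in peptide_psms[rec.accession] if p >= thresholds.min_psms
            )
            ok = good >= thresholds.min_unique_peptides
        else:
            ok = (
                rec.unique_peptides >= thresholds.min_unique_peptides
                and rec.psms >= thresholds.min_psms
            )
        (kept if ok else removed).append(rec)
    logger.info(
        "evidence filter: %d in / %d kept / %d removed",
        len(records), len(kept), len(removed),
    )
    return kept, removed


def collapse_isoforms(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Collapse duplicate gene symbols, keeping the record with most PSMs.

    Network nodes are gene symbols, so isoforms mapping to one symbol must be
    merged before the network join.  Ties on PSM count keep the first record.
    Output preserves the input order of the surviving records.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    n_collapsed = 0
    for rec in records:
        if rec.gene_symbol not in best:
            best[rec.gene_symbol] = rec
            order.append(rec.gene_symbol)
        else:
            n_collapsed += 1
            if rec.psms > best[rec.gene_symbol].psms:
                best[rec.gene_symbol] = rec
    if n_collapsed:
        logger.info("collapsed %d isoform record(s) onto existing symbols", n_collapsed)
    return [best[s] for s in order]


def add_bait(
    records: Sequence[ProteinRecord], bait: ProteinRecord
) -> list[ProteinRecord]:
    """Append the bait protein unless its symbol is already present.

    The bait is flagged (``is_bait=True``) so downstream ranking can include
    or exclude it per configuration.  Adding an already-present bait is a
    no-op with a logged warning.
    """
    if any(r.gene_symbol == bait.gene_symbol for r in records):
        logger.warning("bait %s already present; not added", bait.gene_symbol)
        return list(records)
    flagged = ProteinRecord(
        accession=bait.accession,
        gene_symbol=bait.gene_symbol,
        unique_peptides=bait.unique_peptides,
        psms=bait.psms,
        search_score=bait.search_score,
        is_bait=True,
    )
    return [*records, flagged]


def write_identifications(
    records: Iterable[ProteinRecord], path: str | Path
) -> None:
    """Write records as a TSV with the default column names."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                DEFAULT_COLUMNS["accession"],
                DEFAULT_COLUMNS["gene_symbol"],
                DEFAULT_COLUMNS["unique_peptides"],
                DEFAULT_COLUMNS["psms"],
            ]
        )
        for rec in records:
            writer.writerow(
                [rec.accession, rec.gene_symbol, rec.unique_peptides, rec.psms]
            )
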