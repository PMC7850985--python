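"""Screening the shortlist against boolean annotation tables.

The shortlisted proteins are looked up in annotation tables — tissue
expression, disease association, metastasis association, apoptosis role —
each sourced from a different database, and the final candidates are those
satisfying every criterion of a configured conjunction.

Annotations are three-valued: true, false, or *unannotated* (symbol or cell
absent from the table).  Database lookups are incomplete, so an absent entry
must not be silently treated as a negative; unannotated symbols are reported
separately and never qualify as candidates.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, TextIO

from .errors import ConfigurationError, RowParseError

DEFAULT_TRUTHY = frozenset({"✓", "yes", "y", "true", "1"})
DEFAULT_FALSY = frozenset({"x", "✗", "no", "n", "false", "0"})
DEFAULT_MISSING = frozenset({"", "na", "nd", "?"})


@dataclass
class AnnotationTable:
    """Per-gene boolean flags for named criteria, with provenance labels.

    ``flags[symbol][criterion]`` is True/False where annotated; a missing
    symbol, or a criterion missing for a symbol, means *unannotated* —
    distinct from False.
    """

    criteria: list[str]
    flags: dict[str, dict[str, bool]]
    provenance: dict[str, str] = field(default_factory=dict)

    def lookup(self, symbol: str, criterion: str) -> bool | None:
        if criterion not in self.criteria:
            raise ConfigurationError(
                f"unknown criterion {criterion!r}; available: {self.criteria}"
            )
        return self.flags.get(symbol, {}).get(criterion)


@dataclass
class CandidateReport:
    """Outcome of screening a shortlist against an annotation table."""

    shortlist: list[str]
    conjunction: list[str]
    criterion_counts: dict[str, int]
    #: true-counts of the conjunction prefixes, in order (Venn-style nesting)
    conjunction_counts: list[tuple[tuple[str, ...], int]]
    final_candidates: list[str]
    unannotated: list[str]
    cumulative_ranks: dict[str, int] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    #: per shortlist symbol, the three-valued flag of each conjunct
    conjunct_flags: dict[str, dict[str, bool | None]] = field(default_factory=dict)


def screen_candidates(
    shortlist: Sequence[str],
    annotations: AnnotationTable,
    conjunction: Sequence[str],
    cumulative_ranks: Mapping[str, int] | None = None,
) -> CandidateReport:
    """Screen the shortlist; candidates must satisfy every conjunct.

    Per-criterion true-counts are computed over the whole shortlist; the
    final candidates are the shortlist members annotated True for *every*
    criterion in ``conjunction``, ordered by cumulative rank (when given)
    then symbol.  Symbols unannotated for any conjunct are excluded from
    candidacy and listed separately.
    """
    for c in conjunction:
        if c not in annotations.criteria:
            raise ConfigurationError(
                f"unknown criterion {c!r}; available: {annotations.criteria}"
            )
    counts = {
        c: sum(1 for s in shortlist if annotations.lookup(s, c) is True)
        for c in annotations.criteria
    }
    prefix_counts: list[tuple[tuple[str, ...], int]] = []
    for k in range(1, len(conjunction) + 1):
        prefix = tuple(conjunction[:k])
        n = sum(
            1
            for s in shortlist
            if all(annotations.lookup(s, c) is True for c in prefix)
        )
        prefix_counts.append((prefix, n))
    unannotated = [
        s
        for s in shortlist
        if any(annotations.lookup(s, c) is None for c in conjunction)
    ]
    finals = [
        s
        for s in shortlist
        if all(annotations.lookup(s, c) is True for c in conjunction)
    ]
    ranks = dict(cumulative_ranks or {})
    finals.sort(key=lambda s: (ranks.get(s, len(shortlist) + 1), s))
    return CandidateReport(
        shortlist=list(shortlist),
        conjunction=list(conjunction),
        criterion_counts=counts,
        conjunction_counts=prefix_counts,
        final_candidates=finals,
        unannotated=unannotated,
        cumulative_ranks={s: ranks[s] for s in finals if s in ranks},
        provenance=dict(annotations.provenance),
        conjunct_flags={
            s: {c: annotations.lookup(s, c) for c in conjunction}
            for s in shortlist
        },
    )


def parse_annotations(
    source: str | Path | TextIO,
    truthy: frozenset[str] = DEFAULT_TRUTHY,
    falsy: frozenset[str] = DEFAULT_FALSY,
    missing: frozenset[str] = DEFAULT_MISSING,
    provenance: Mapping[str, str] | None = None,
) -> AnnotationTable:
    """Parse a delimited annotation table with configurable truth tokens.

    First column is the gene symbol; remaining header names are the
    criteria.  Tokens are matched case-insensitively against the truthy,
    falsy and missing sets; any other token is a row error, and duplicate
    symbols are an error.
    """
    if isinstance(source, (str, Path)):
        fh: TextIO = open(source, "r", encoding="utf-8", newline="")
        owned = True
    else:
        fh, owned = source, False
    try:
        first = fh.readline()
        if not first:
            raise ConfigurationError("annotation table is empty (no header)")
        delim = "\t" if "\t" in first else ","
        header = next(csv.reader(io.StringIO(first), delimiter=delim))
        criteria = [h.strip() for h in header[1:]]
        if not criteria:
            raise ConfigurationError("annotation table has no criterion columns")
        flags: dict[str, dict[str, bool]] = {}
        bad: list[tuple[int, str]] = []
        for row_no, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row or all(not c.strip() for c in row):
                continue
            symbol = row[0].strip()
            if symbol in flags:
                raise RowParseError(
                    "duplicate gene symbol", [(row_no, f"{symbol!r} repeated")]
                )
            cells: dict[str, bool] = {}
            for crit, raw in zip(criteria, row[1:]):
                token = raw.strip().lower()
                raw_token = raw.strip()
                if raw_token in truthy or token in truthy:
                    cells[crit] = True
                elif raw_token in falsy or token in falsy:
                    cells[crit] = False
                elif token in missing:
                    continue  # unannotated cell
                else:
                    bad.append((row_no, f"unmapped token {raw!r} for {crit!r}"))
            flags[symbol] = cells
        if bad:
            raise RowParseError("invalid annotation rows", bad)
        return AnnotationTable(
            criteria=criteria, flags=flags, provenance=dict(provenance or {})
        )
    finally:
        if owned:
            fh.close()


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    """Write an annotation table as TSV with ``yes``/``no`` tokens."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["symbol", *table.criteria])
        for symbol in sorted(table.flags):
            row = [symbol]
            for crit in table.criteria:
                val = table.flags[symbol].get(crit)
                row.append("" if val is None else ("yes" if val else "no"))
            writer.writerow(row)


def format_report(report: CandidateReport) -> str:
    """Human-readable candidate report."""
    lines = [
        f"Shortlist: {len(report.shortlist)} proteins",
        "",
        "Per-criterion counts over the shortlist:",
    ]
    for crit, n in report.criterion_counts.items():
        src = report.provenance.get(crit, "")
        suffix = f"  [{src}]" if src else ""
        lines.append(f"  {crit}: {n}{suffix}")
    lines.append("")
    lines.append("Conjunction (nested intersections):")
    for prefix, n in report.conjunction_counts:
        lines.append(f"  {' ∧ '.join(prefix)}: {n}")
    if report.unannotated:
        lines.append("")
        lines.append(
            "Unannotated for ≥1 conjunct (excluded from candidacy): "
            + ", ".join(report.unannotated)
        )
    lines.append("")
    if report.final_candidates:
        named = ", ".join(
            f"{s} (cumulative rank {report.cumulative_ranks[s]})"
            if s in report.cumulative_ranks
            else s
            for s in report.final_candidates
        )
        lines.append(f"Final candidates: {named}")
    else:
        lines.append("Final candidates: none")
    return "\n".join(lines) + "\n"


def write_report(report: CandidateReport, txt_path: str | Path, tsv_path: str | Path) -> None:
    """Write the text report and a per-protein flag TSV."""
    Path(txt_path).write_text(format_report(report), encoding="utf-8")
    with open(tsv_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein", "is_candidate", *report.conjunction])
        candidates = set(report.final_candidates)
        for s in report.shortlist:
            flags = report.conjunct_flags.get(s, {})
            cells = [
                ""
                if flags.get(c) is None
                else ("yes" if flags.get(c) else "no")
                for c in report.conjunction
            ]
            writer.writerow([s, "yes" if s in candidates else "no", *cells])
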