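"""Exception hierarchy shared across the pipeline stages."""

from __future__ import annotations


class PipelineError(Exception):
    """Base class for all errors raised by netprio."""


class ConfigurationError(PipelineError):
    """A parameter, column mapping or criterion name is invalid."""


class RowParseError(PipelineError):
    """One or more input rows could not be parsed.

    Carries ``rows``: a list of ``(row_number, message)`` pairs, 1-based and
    counted over the whole file including the header, so the offending lines
    can be located in the original input.
    """

    def __init__(self, message: str, rows: list[tuple[int, str]]):
        self.rows = rows
        detail = "; ".join(f"row {n}: {m}" for n, m in rows)
        super().__init__(f"{message}: {detail}")


class EmptyNetworkError(PipelineError):
    """Every edge was rejected; the resulting network would have no edges."""
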