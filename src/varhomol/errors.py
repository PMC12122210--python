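"""Exception hierarchy.

Errors are split by contract: parse errors carry a line number, structural
errors describe an alignment-level inconsistency, content errors a bad
residue, schema errors a bad table, consistency errors a variant that
contradicts its alignment.
"""


class VarhomolError(Exception):
    """Base class for all package errors."""


class StockholmParseError(VarhomolError):
    """Malformed Stockholm syntax; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AlignmentStructureError(VarhomolError):
    """Rows of one record disagree (lengths, span vs residue count, duplicates)."""


class ContentError(VarhomolError):
    """A character that is neither a canonical amino acid nor a gap."""


class SchemaError(VarhomolError):
    """A variant/protein table is missing required columns or has bad rows."""


class ConsistencyError(VarhomolError):
    """A variant's stated reference residue contradicts the alignment."""


class GenerationError(VarhomolError):
    """A synthetic-family spec is infeasible or its invariants failed post-checks."""
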