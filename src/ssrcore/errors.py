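"""Exception hierarchy.

Three broad classes are distinguished so that callers (and the CLI exit
codes) can separate "the file is malformed" from "the data violates a
domain invariant" from "the computation is undefined on this input".
"""


class SSRCoreError(Exception):
    """Base class for all package errors."""


class ParseError(SSRCoreError):
    """Malformed input file; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SSRCoreError):
    """Structurally valid input that violates a domain invariant."""


class ComputationError(SSRCoreError):
    """An operation is undefined for the given (valid) data."""


class AllMissingLocusError(ComputationError):
    """A locus has no non-missing genotype, so frequencies are undefined."""


class NoSharedLociError(ComputationError):
    """Two accessions have no locus typed in both; distance undefined."""


class InfiniteDistanceError(ComputationError):
    """A distance matrix contains infinite entries where finite ones are required."""
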