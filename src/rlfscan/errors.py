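"""Exception hierarchy.

Three error families map onto the CLI's distinct exit codes: bad parameter
values, malformed input files, and I/O failures (plain OSError is reused for
the last).
"""


class RlfsError(Exception):
    """Base class for all package errors."""


class ParameterError(RlfsError, ValueError):
    """A parameter value violates its documented constraint."""


class FormatError(RlfsError, ValueError):
    """Malformed input data; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
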