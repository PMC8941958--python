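"""Exception hierarchy shared across the package."""


class SynclockError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SynclockError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlignmentError(SynclockError):
    """Sequences that are supposed to form an alignment do not."""


class SaturationError(SynclockError):
    """A distance is beyond the domain of the correction formula."""


class DomainError(SynclockError):
    """A model was evaluated outside its parameter domain."""
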