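"""Exception types shared across the package."""


class RoseqError(Exception):
    """Base class for all roseq-specific errors."""


class ParseError(RoseqError):
    """A text input (BED, bedGraph, ...) could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(RoseqError):
    """An input violated a structural invariant (e.g. end <= start)."""


class DegenerateSignalError(RoseqError):
    """A signal is constant (zero dynamic range) and cannot be normalized."""
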