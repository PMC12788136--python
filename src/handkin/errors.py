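"""Exception types shared across the toolkit."""


class HandkinError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(HandkinError, ValueError):
    """A precondition or data invariant was violated."""


class AlignmentError(ValidationError):
    """Predicted and ground-truth trajectories are not frame-aligned.

    Raised when fps, frame count or joint sets differ; resample one
    trajectory onto the other's timebase before computing metrics.
    """


class ParseError(HandkinError, ValueError):
    """A trajectory file could not be parsed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
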