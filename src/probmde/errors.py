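"""Exception types shared across the package."""


class ProbmdeError(Exception):
    """Base class for all package errors."""


class FormatError(ProbmdeError, ValueError):
    """Malformed input file (count table, annotation, tag map)."""


class QuestionParseError(ProbmdeError, ValueError):
    """Invalid question string; carries the offending token position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class DomainError(ProbmdeError, ValueError):
    """Argument outside its mathematical domain (e.g. N > T, pi outside (0,1))."""
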