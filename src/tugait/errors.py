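"""Exception hierarchy for the tugait pipeline."""

from __future__ import annotations


class TugaitError(Exception):
    """Base class for all tugait errors."""


class FormatError(TugaitError):
    """A file does not have the expected layout (missing column, empty, ...)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class DegenerateInputError(TugaitError):
    """Input too small or too trivial for the requested operation."""


class ParameterError(TugaitError, ValueError):
    """A parameter is outside its documented range."""


class ValidationError(TugaitError, ValueError):
    """A domain object violates its invariants."""


class DegenerateSpectrumError(TugaitError):
    """Spectrum has too few admissible bins for peak extraction."""


class SegmentationFailure(TugaitError):
    """Automatic trial segmentation did not find exactly three trials.

    Carries the surviving candidate segments so a caller can inspect them
    and, if appropriate, supply a manual override.
    """

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates or [])


class MissingArtifactError(TugaitError, FileNotFoundError):
    """An expected upstream pipeline artifact is absent."""
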