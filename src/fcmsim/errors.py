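"""Exception hierarchy for fcmsim.

All package errors derive from :class:`FcmError` so callers can catch one
type at the boundary (the CLI maps them onto exit codes).
"""


class FcmError(Exception):
    """Base class for all fcmsim errors."""


class NetworkFormatError(FcmError):
    """A network file or record could not be parsed."""


class MalformedWeightError(NetworkFormatError):
    """An influence weight is outside [-1, 1], zero, or not a number/'I'."""


class DuplicateEdgeError(NetworkFormatError):
    """More than one influence for an ordered (source, target) pair."""


class UnknownConceptError(FcmError):
    """A concept id does not exist in the target network."""


class UndefinedFractionError(FcmError):
    """Positive fraction requested on a network with no determinate edges."""


class UndefinedSimilarityError(FcmError):
    """Cosine similarity requested against a zero vector."""


class EnginePreconditionError(FcmError):
    """The engine was handed invalid inputs (e.g. unresolved 'I' weights)."""


class NumericalFailureError(FcmError):
    """A state component became non-finite during iteration."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"non-finite state at iteration {iteration}")


class DegenerateTestError(FcmError):
    """A statistical test is undefined for the given data (e.g. zero-variance
    paired differences)."""
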