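"""Exception hierarchy for the eeai pipeline.

Every stage raises a subclass of :class:`EEAIError` so that pipeline drivers
can attach the stage name and keep going or abort cleanly.
"""


class EEAIError(Exception):
    """Base class for all eeai errors."""


class CageFormatError(EEAIError):
    """Input table is malformed (missing column, unknown dialect, bad header)."""


class SamplingError(EEAIError):
    """Timestamps are not uniformly spaced beyond tolerance."""


class DuplicateSampleError(EEAIError):
    """Two rows share the same (animal, timestamp) key."""


class InsufficientDataError(EEAIError):
    """Recording too short for the requested analysis window."""

    def __init__(self, message: str, available_h: float | None = None):
        super().__init__(message)
        self.available_h = available_h


class ParameterError(EEAIError):
    """Invalid parameter value (amplitude fraction > 1, n = 0, k > p, ...)."""


class CoverageError(EEAIError):
    """Time window too short to cover the requested period range."""


class ConditioningError(EEAIError):
    """Singular or near-singular design matrix in a least-squares fit."""


class WindowingError(EEAIError):
    """Analysis window is not a whole number of days."""


class AssemblyError(EEAIError):
    """A feature-table row cannot be assembled (missing rhythm fit or weight)."""


class SchemaError(EEAIError):
    """A table does not carry the columns a fitted model requires."""
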