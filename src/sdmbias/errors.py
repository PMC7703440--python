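"""Exception hierarchy for the sdmbias package."""


class SdmBiasError(Exception):
    """Base class for all package-specific errors."""


class InvalidExtentError(SdmBiasError, ValueError):
    """Grid extent has fewer than two active cells or malformed inputs."""


class DegenerateFieldError(SdmBiasError, ValueError):
    """A spatial field with zero variance cannot be autocorrelation-tested."""


class DisconnectedExtentError(SdmBiasError, ValueError):
    """No rook-contiguous neighbour pair exists on the extent."""


class EmptyEffortError(SdmBiasError, ValueError):
    """A record-count vector with zero total effort."""


class PartitionInfeasibleError(SdmBiasError, ValueError):
    """Fewer spatial blocks than cross-validation folds."""


class InvalidParameterError(SdmBiasError, ValueError):
    """A parameter outside its admissible range."""


class CalibrationError(SdmBiasError, RuntimeError):
    """Bisection failed to reach the requested target statistic."""


class AlignmentError(SdmBiasError, ValueError):
    """External layer or record data does not align with the grid."""


class InsufficientEnvironmentError(SdmBiasError, ValueError):
    """Too few environmental layers to draw a species response."""


class GenerationStuckError(SdmBiasError, RuntimeError):
    """Rejection sampling for a virtual species exceeded its retry budget."""


class InvalidRequestError(SdmBiasError, ValueError):
    """A request for more items than exist (e.g. species subsampling)."""


class UnsampleableCommunityError(SdmBiasError, RuntimeError):
    """The bias template puts no weight on any occupied cell."""


class ParseError(SdmBiasError, ValueError):
    """Malformed external table; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ConfigurationError(SdmBiasError, ValueError):
    """Invalid model configuration (e.g. wrong number of predictors)."""


class UnavailablePredictionError(SdmBiasError, RuntimeError):
    """Prediction requested from a skipped or failed model fit."""


class UndefinedMetricError(SdmBiasError, ValueError):
    """Metric undefined because only one class is present."""


class InsufficientDataError(SdmBiasError, ValueError):
    """Too few evaluated results for the requested meta-analysis."""
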