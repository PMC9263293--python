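"""Exception hierarchy used across the pipeline."""


class PLVNetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PLVNetError, ValueError):
    """A numeric or structural parameter is outside its valid domain."""


class ConfigurationError(PLVNetError, ValueError):
    """A run or cohort configuration is internally inconsistent."""


class RecordingLengthError(PLVNetError, ValueError):
    """A recording is too short for the requested segmentation."""


class ParseError(PLVNetError, ValueError):
    """A file could not be parsed in the declared format."""


class MontageError(PLVNetError, ValueError):
    """Channel labels do not match the montage."""


class UndefinedPhaseError(PLVNetError, ValueError):
    """Instantaneous phase is undefined (zero-variance signal)."""


class DegenerateNetworkError(PLVNetError, ValueError):
    """Thresholding produced a network with no edges."""


class DisconnectedNetworkError(PLVNetError, ValueError):
    """A metric is undefined because no node pair is connected."""


class UndefinedCorrelationError(PLVNetError, ValueError):
    """Correlation is undefined (constant input)."""


class SubjectMismatchError(PLVNetError, ValueError):
    """Metric table and cohort table do not share subject ids."""
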