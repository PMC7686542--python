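"""Exception hierarchy for gcflow.

Every anticipated user-facing failure gets its own named class so that
callers (and tests) can catch precisely the condition they care about.
"""


class GCFlowError(Exception):
    """Base class for all gcflow errors."""


class PartitionError(GCFlowError):
    """Invalid network partition."""


class DuplicateROIError(PartitionError):
    """The same ROI label appears more than once."""


class UnknownNetworkError(PartitionError):
    """A network token is not one of the six recognised subsystems."""


class MissingROIError(GCFlowError):
    """A required ROI column is absent from a time-series table."""


class NonNumericError(GCFlowError):
    """A time-series table contains a non-numeric cell."""


class GroupSizeError(GCFlowError):
    """A group has too few subjects for the requested analysis."""


class RankDeficientError(GCFlowError):
    """A regression design matrix is rank deficient."""


class BandError(GCFlowError):
    """A bandpass specification is outside (0, Nyquist)."""


class ConstantSeriesError(GCFlowError):
    """A series has zero variance where variation is required."""


class ShortSeriesError(GCFlowError):
    """A series is too short for the requested model order or window."""


class UnstableCouplingError(GCFlowError):
    """A VAR coupling matrix is (or cannot be rescaled to be) stationary."""


class WindowError(GCFlowError):
    """Invalid sliding-window specification."""


class ShapeMismatchError(GCFlowError):
    """Array shapes or label sets do not agree."""
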