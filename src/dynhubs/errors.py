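"""Exception hierarchy for dynhubs.

All package errors derive from :class:`DynHubsError` so callers can catch
everything with one clause; each subclass also derives from the closest
builtin (ValueError/RuntimeError) for idiomatic handling.
"""


class DynHubsError(Exception):
    """Base class for all dynhubs errors."""


class InvalidConfigError(DynHubsError, ValueError):
    """A configuration value is out of range or inconsistent."""


class InvalidInputError(DynHubsError, ValueError):
    """An input array/table violates a documented precondition."""


class DegenerateSignalError(DynHubsError, ValueError):
    """A time series has zero variance after a leave-one-out deletion.

    Carries the offending edge (pair of 0-based region indices, or a single
    region) and the deleted time point, when known.
    """

    def __init__(self, message, *, edge=None, timepoint=None):
        super().__init__(message)
        self.edge = edge
        self.timepoint = timepoint


class GenerationError(DynHubsError, RuntimeError):
    """Synthetic-data generation failed (e.g. a non-repairable covariance)."""


class UndefinedResultError(DynHubsError, ValueError):
    """The requested quantity is undefined for this input (e.g. mean overlap
    with fewer than two valid time points)."""


class ParseError(DynHubsError, ValueError):
    """A data file could not be parsed; the message names the location."""
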