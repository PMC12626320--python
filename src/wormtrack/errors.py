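"""Exception hierarchy shared across the package."""


class WormtrackError(Exception):
    """Base class for all package-specific errors."""


class InvalidBoxError(WormtrackError, ValueError):
    """A bounding box with non-positive width or height."""


class MissingCalibrationError(WormtrackError, ValueError):
    """A normalized-coordinate conversion was requested without image dimensions."""


class ConfigError(WormtrackError, ValueError):
    """A configuration value violates its documented constraint."""


class InconsistentInputError(WormtrackError, ValueError):
    """Inputs that must agree (frame indices, series lengths) do not."""


class NumericalStateError(WormtrackError, ValueError):
    """A filter state became non-finite."""


class InvalidCostError(WormtrackError, ValueError):
    """An assignment cost matrix contains non-finite entries."""


class OrderingError(WormtrackError, ValueError):
    """Frames were presented out of increasing order."""


class ZeroIntervalError(WormtrackError, ValueError):
    """A time interval of zero length where a positive duration is required."""


class InsufficientDataError(WormtrackError, ValueError):
    """Too few samples for the requested estimator."""


class ParseError(WormtrackError, ValueError):
    """A detection or track file line could not be parsed."""
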