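"""Exception hierarchy shared across the package."""


class RedoxLanError(Exception):
    """Base class for all redoxlan-specific errors."""


class CalibrationRangeError(RedoxLanError, ValueError):
    """A predictor value lies outside the calibration's convention range."""


class NonInvertibleCalibrationError(RedoxLanError, ValueError):
    """The calibration line has zero slope and cannot be inverted."""


class InsufficientDataError(RedoxLanError, ValueError):
    """Too few observations to fit the requested model."""


class DegenerateDesignError(RedoxLanError, ValueError):
    """All predictor values coincide; the regression design is singular."""


class ParameterDomainError(RedoxLanError, ValueError):
    """A model parameter violates its admissible domain."""


class UndefinedStatisticError(RedoxLanError, ValueError):
    """The requested statistic is undefined for the given input (e.g. zero variance)."""


class TimeSeriesFormatError(RedoxLanError, ValueError):
    """A time-series table violates the expected layout."""


class IntegrationError(RedoxLanError, RuntimeError):
    """The ODE solver failed to advance the solution."""


class ConfigError(RedoxLanError, ValueError):
    """A pipeline configuration is invalid or references missing files."""
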