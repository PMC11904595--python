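"""Package exception hierarchy."""


class GolgiRedoxError(Exception):
    """Base class for all package errors."""


class InvalidCalibrationError(GolgiRedoxError, ValueError):
    """A sensor or fluorescence calibration is degenerate or unusable."""


class InsufficientDataError(GolgiRedoxError, ValueError):
    """Too few observations or calibration points for the requested fit."""


class OutOfRangeError(GolgiRedoxError, ValueError):
    """A value lies outside the domain of the requested computation."""


class UndefinedRatioError(GolgiRedoxError, ZeroDivisionError):
    """A label ratio is undefined (zero reference area)."""


class MassValidationError(GolgiRedoxError, ValueError):
    """A computed target m/z disagrees with its reference value."""


class SimulationError(GolgiRedoxError, RuntimeError):
    """A synthetic scene could not be generated under the given constraints."""


class ConfigError(GolgiRedoxError, ValueError):
    """A pipeline configuration is invalid."""
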