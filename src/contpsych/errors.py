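"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems -> 2,
data problems -> 3, fit failures -> 4.
"""


class ContpsychError(Exception):
    """Base class for all package errors."""


class ConfigError(ContpsychError):
    """Invalid configuration or parameter values."""

    exit_code = 2


class DegenerateModelError(ConfigError):
    """Model parameters leave a quantity undefined (e.g. both variances zero)."""


class StabilityError(ConfigError):
    """The action system diverged for the given (b, c, dt) configuration."""


class DataError(ContpsychError):
    """Malformed or insufficient input data."""

    exit_code = 3


class DataFormatError(DataError):
    """A delimited-text series file violates the expected format."""


class CoverageError(DataError):
    """No candidate random walk covered the requested direction space."""


class InsufficientDataError(DataError):
    """Too few observations for the requested operation."""


class FitError(ContpsychError):
    """A model fit failed or is unidentifiable."""

    exit_code = 4


class FitFailureError(FitError):
    """Optimizer did not converge to an acceptable solution."""


class UnidentifiableError(FitError):
    """The data carry no information about the requested parameter."""
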