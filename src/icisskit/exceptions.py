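"""Exception types shared across the package."""


class IcissError(Exception):
    """Base class for package errors."""


class ConfigError(IcissError):
    """Invalid configuration (distribution spec, mapping, dates, ...)."""


class SeparationError(IcissError):
    """Perfect separation detected while fitting a logistic model."""


class ConvergenceError(IcissError):
    """Logistic fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DegenerateStatisticError(IcissError):
    """A statistic is undefined for the given input (e.g. single-class y)."""


class EmptyDataError(IcissError):
    """An operation received no rows to work on."""
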