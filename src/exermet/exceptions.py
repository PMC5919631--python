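"""Exception types shared across the package."""


class ExermetError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ExermetError, ValueError):
    """An input lies outside the physiological validity range of an equation."""


class TableLookupError(ExermetError, KeyError):
    """A normative-table key (gender, age bracket, fitness category) is missing."""


class CalibrationError(ExermetError, ValueError):
    """Steady-state calibration of a derived constant failed or is inconsistent."""


class SolverFailure(ExermetError, RuntimeError):
    """The ODE integrator failed before reaching the end of the horizon."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class IdentifiabilityError(ExermetError, ValueError):
    """The weighted sensitivity matrix is rank deficient at the optimum."""
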