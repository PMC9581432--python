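"""Exception hierarchy for exerdyn.

All package-specific failures derive from :class:`ExerdynError` so callers
(and the CLI) can catch one base class. Validation errors additionally
derive from :class:`ValueError` to behave naturally in generic code.
"""


class ExerdynError(Exception):
    """Base class for all exerdyn errors."""


class InvalidStateError(ExerdynError, ValueError):
    """A compartment count is negative, NaN, or infinite."""


class DegeneratePopulationError(ExerdynError, ValueError):
    """Total population N is zero or negative; mass-action terms undefined."""


class InvalidParameterError(ExerdynError, ValueError):
    """A rate constant is negative, NaN, or infinite."""


class CaseMismatchError(ExerdynError, ValueError):
    """A special-case R0 formula was called with parameters outside the
    zeroing pattern that makes the reduction valid."""


class DegenerateFormulaError(ExerdynError, ZeroDivisionError):
    """The general closed-form R0 is undefined (leading coefficient A = 0);
    a special-case formula must be used instead."""


class FormulaDomainError(ExerdynError, ValueError):
    """The R0 quadratic has a genuinely negative discriminant."""


class NonInvertibleTransitionError(ExerdynError, ValueError):
    """The NGM transition matrix V is singular."""


class DfeNotEquilibriumError(ExerdynError, ValueError):
    """Spontaneous uptake (gamma1 or gamma2 > 0) makes the all-sedentary
    state a non-equilibrium; the next-generation construction does not apply."""


class IntegrationError(ExerdynError, RuntimeError):
    """The ODE integrator failed or violated a trajectory post-condition."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


class UndefinedChangeError(ExerdynError, ZeroDivisionError):
    """Percent change relative to a zero baseline is undefined."""


class ConfigError(ExerdynError, ValueError):
    """A run configuration file is malformed or violates an invariant."""
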