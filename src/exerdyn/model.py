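"""Core compartmental model of exercise behavior in a closed population.

The population is split into three compartments:

* ``S``  — sedentary individuals (< 150 min/week of moderate activity),
* ``E1`` — moderately active individuals (150–300 min/week),
* ``E2`` — extremely active individuals (> 300 min/week).

Flows between compartments are either *social* (mass-action contact terms
scaled by the total population ``N``, in the Kermack–McKendrick tradition)
or *spontaneous* (linear terms). The system is

.. math::

    S'   &= \\beta_1 S E_1/N + \\beta_2 S E_2/N + \\delta_1 E_1 + \\delta_2 E_2
            - (r_1 + k_1) S E_1/N - (r_2 + k_2) S E_2/N
            - (\\gamma_1 + \\gamma_2) S \\\\
    E_1' &= r_1 S E_1/N + r_2 S E_2/N + \\gamma_1 S - \\beta_1 S E_1/N
            - \\delta_1 E_1 - \\alpha_2 E_1 + \\alpha_1 E_2 \\\\
    E_2' &= k_1 S E_1/N + k_2 S E_2/N + \\gamma_2 S - \\beta_2 S E_2/N
            - \\delta_2 E_2 + \\alpha_2 E_1 - \\alpha_1 E_2

There is no demography (births, deaths, migration), so the total
``N = S + E1 + E2`` is conserved exactly by construction: every flow term
appears once with each sign across the three equations.

The inter-exerciser exchange terms are linear (``alpha1 * E2`` and
``alpha2 * E1``), not mass-action products, even though they model a social
mechanism; the linear form is what the model's threshold analysis is built
on.

All rates are per week; compartment sizes are real-valued person counts
(continuum approximation, no integer rounding).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import (
    DegeneratePopulationError,
    InvalidParameterError,
    InvalidStateError,
)

#: Names of the twelve nonnegative rate constants, in canonical order.
PARAMETER_NAMES: tuple[str, ...] = (
    "r1", "r2", "k1", "k2",
    "gamma1", "gamma2",
    "beta1", "beta2",
    "delta1", "delta2",
    "alpha1", "alpha2",
)


@dataclass(frozen=True)
class ModelParameters:
    """The twelve nonnegative rate constants of the model, in week^-1.

    Parameters
    ----------
    r1, r2
        Social uptake S -> E1 driven by contact with E1 (``r1``) or E2 (``r2``).
    k1, k2
        Social uptake S -> E2 driven by contact with E1 (``k1``) or E2 (``k2``).
    gamma1, gamma2
        Spontaneous uptake S -> E1 and S -> E2 (e.g. physician's advice).
    beta1, beta2
        Social recidivism E1 -> S and E2 -> S driven by contact with S.
    delta1, delta2
        Spontaneous recidivism E1 -> S and E2 -> S (e.g. injury).
    alpha1, alpha2
        Exchange between active compartments: E2 -> E1 (``alpha1``) and
        E1 -> E2 (``alpha2``).
    """

    r1: float = 0.0
    r2: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    delta1: float = 0.0
    delta2: float = 0.0
    alpha1: float = 0.0
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"rate constant {name!r} must be finite, got {value!r}"
                )
            if value < 0:
                raise InvalidParameterError(
                    f"rate constant {name!r} must be >= 0, got {value!r}"
                )
            object.__setattr__(self, name, float(value))

    def as_dict(self) -> dict[str, float]:
        """Return the parameters as an ordered name -> value mapping."""
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def replace(self, **updates: float) -> "ModelParameters":
        """Return a copy with the named rate constants replaced."""
        return dataclasses.replace(self, **updates)


@dataclass(frozen=True)
class PopulationState:
    """Compartment sizes at one time point, in persons.

    The total ``N = S + E1 + E2`` is derived, never stored, so conservation
    is a checkable property of the dynamics rather than an assumption.
    """

    t: float
    S: float
    E1: float
    E2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise InvalidStateError(f"time must be finite, got {self.t!r}")
        for name in ("S", "E1", "E2"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidStateError(
                    f"compartment {name} must be finite, got {value!r}"
                )
            if value < 0:
                raise InvalidStateError(
                    f"compartment {name} must be >= 0, got {value!r}"
                )
        if self.S + self.E1 + self.E2 <= 0:
            raise DegeneratePopulationError(
                "total population N = S + E1 + E2 must be > 0"
            )

    @property
    def N(self) -> float:
        """Total population size."""
        return self.S + self.E1 + self.E2

    def fractions(self) -> tuple[float, float, float]:
        """Compartment sizes as fractions of the total, ``(S, E1, E2)/N``."""
        n = self.N
        return (self.S / n, self.E1 / n, self.E2 / n)


@dataclass(frozen=True)
class Scenario:
    """A complete simulation setup: parameters, initial state, horizon."""

    params: ModelParameters
    initial: PopulationState
    horizon: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.initial.t != 0:
            raise InvalidStateError(
                f"scenario initial state must have t = 0, got t = {self.initial.t}"
            )
        if not (math.isfinite(self.horizon) and self.horizon > 0):
            raise InvalidStateError(
                f"scenario horizon must be a positive number of weeks, got {self.horizon!r}"
            )


def rhs_raw(params: ModelParameters, S: float, E1: float, E2: float) -> tuple[float, float, float]:
    """Evaluate the right-hand side from raw compartment values.

    No validation is performed; this is the fast path used inside the ODE
    integrator, where transient tiny negative values are the solver's
    business. ``N`` is recomputed as ``S + E1 + E2`` on every call.
    """
    N = S + E1 + E2
    # each social flow computed once so that every term cancels exactly
    # in the conservation sum
    se1 = S * E1 / N
    se2 = S * E2 / N
    f_r1 = params.r1 * se1       # S -> E1, contact with E1
    f_r2 = params.r2 * se2       # S -> E1, contact with E2
    f_k1 = params.k1 * se1       # S -> E2, contact with E1
    f_k2 = params.k2 * se2       # S -> E2, contact with E2
    f_g1 = params.gamma1 * S     # S -> E1, spontaneous
    f_g2 = params.gamma2 * S     # S -> E2, spontaneous
    f_b1 = params.beta1 * se1    # E1 -> S, contact with S
    f_b2 = params.beta2 * se2    # E2 -> S, contact with S
    f_d1 = params.delta1 * E1    # E1 -> S, spontaneous
    f_d2 = params.delta2 * E2    # E2 -> S, spontaneous
    f_a1 = params.alpha1 * E2    # E2 -> E1 (linear, as the model defines it)
    f_a2 = params.alpha2 * E1    # E1 -> E2

    dS = f_b1 + f_b2 + f_d1 + f_d2 - f_r1 - f_r2 - f_k1 - f_k2 - f_g1 - f_g2
    dE1 = f_r1 + f_r2 + f_g1 - f_b1 - f_d1 - f_a2 + f_a1
    dE2 = f_k1 + f_k2 + f_g2 - f_b2 - f_d2 + f_a2 - f_a1
    return dS, dE1, dE2


def rhs(params: ModelParameters, state: PopulationState) -> tuple[float, float, float]:
    """Time derivatives ``(dS/dt, dE1/dt, dE2/dt)`` in persons per week.

    Raises
    ------
    InvalidStateError
        If a compartment is negative or non-finite.
    DegeneratePopulationError
        If ``N = 0`` (mass-action denominators undefined).
    """
    # PopulationState validates on construction, so a state instance is
    # already known-good; re-check here in case of frozen-instance abuse.
    if state.N <= 0:
        raise DegeneratePopulationError("total population N must be > 0")
    return rhs_raw(params, state.S, state.E1, state.E2)


def is_equilibrium(
    params: ModelParameters, state: PopulationState, tol: float = 1e-12
) -> bool:
    """True iff every component of the right-hand side has magnitude <= tol."""
    if tol < 0:
        raise ValueError(f"tol must be >= 0, got {tol}")
    return max(abs(d) for d in rhs(params, state)) <= tol
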