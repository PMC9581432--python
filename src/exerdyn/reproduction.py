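"""Basic reproduction number R0 and the persistence threshold.

R0 plays the same role here as in epidemic models: physical activity is the
"transmitted" state. If R0 < 1 the active compartments decay to zero and the
population ends up entirely sedentary; if R0 > 1 the active compartments
plateau at a positive level ("exercise persists").

The general R0 is the larger root of the quadratic ``A x^2 - B x + C = 0``,

.. math:: R_0 = \\frac{B + \\sqrt{B^2 - 4AC}}{2A},

with coefficients built from the rate constants, the initial sedentary count
``S0`` and the total ``N``:

.. math::

    A &= N^2(\\alpha_1\\delta_1 + \\delta_2(\\alpha_2+\\delta_1))
         + N S_0(\\beta_1(\\alpha_1+\\delta_2) + \\beta_2(\\alpha_2+\\delta_1))
         + S_0^2\\beta_1\\beta_2 \\\\
    B &= S_0[N(\\alpha_1 k_1 + \\delta_1 k_2)
         + N(\\alpha_2(k_2+r_2) + r_1(\\alpha_1+\\delta_2))
         + S_0(\\beta_1 k_2 + \\beta_2 r_1)] \\\\
    C &= (r_1 k_2 - r_2 k_1) S_0^2

The spontaneous uptake rates gamma1, gamma2 do not enter A, B or C: the
next-generation accounting counts only socially transmitted activity.

Three analytically tractable special cases:

* **Case 1** (no social transmission, ``r1 = r2 = k1 = k2 = 0``): R0 = 0.
* **Case 2** (``r2 = k2 = beta2 = gamma1 = gamma2 = delta1 = delta2 = 0``):
  R0 = (k1 + r1) / beta1.
* **Case 3** (``r2 = k2 = beta2 = gamma1 = gamma2 = delta2 = 0``):
  R0 = (k1 + r1) p / (beta1 p + delta1), with p = S0/N the sedentary
  fraction; persistence iff (k1 + r1) p > beta1 p + delta1.

:func:`r0_ngm` rebuilds R0 numerically from the next-generation matrix as an
independent cross-check: R0 = spectral radius of F V^{-1}, where F collects
the linearized creation of active individuals out of the sedentary pool
(the r and k contact terms) and V the linearized removals and exchanges
(beta, delta, alpha terms). This split is the one that reproduces the
closed form above.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    CaseMismatchError,
    DegenerateFormulaError,
    DegeneratePopulationError,
    DfeNotEquilibriumError,
    FormulaDomainError,
    NonInvertibleTransitionError,
)
from .model import ModelParameters

#: Half-width of the band around R0 = 1 classified as "threshold".
THRESHOLD_EPS = 1e-9

#: Relative tolerance for clamping a floating-point-negative discriminant.
_DISC_CLAMP_REL = 1e-12


class Persistence(str, enum.Enum):
    """Long-run fate of the physically active compartments."""

    PERSISTENCE = "persistence"
    EXTINCTION = "extinction"
    THRESHOLD = "threshold"


class R0Method(str, enum.Enum):
    CLOSED_FORM = "closed_form"
    CASE1 = "case1"
    CASE2 = "case2"
    CASE3 = "case3"
    NGM = "ngm"


@dataclass(frozen=True)
class QuadraticCoefficients:
    """Coefficients A, B, C of the R0 quadratic ``A x^2 - B x + C = 0``."""

    A: float
    B: float
    C: float


@dataclass(frozen=True)
class R0Result:
    """A computed basic reproduction number.

    ``persistence_inequality`` is populated only by :func:`r0_case3`, where
    the threshold condition has the printed closed form
    ``(k1 + r1) p > beta1 p + delta1``; it always agrees with ``value > 1``.
    """

    value: float
    method: R0Method
    classification: Persistence
    coefficients: QuadraticCoefficients | None = None
    persistence_inequality: bool | None = None


def classify_persistence(r0_value: float) -> Persistence:
    """Classify an R0 value against the persistence threshold at 1.

    Values within ``THRESHOLD_EPS`` of 1 are reported as ``threshold``
    rather than being folded into either side.
    """
    if not math.isfinite(r0_value) or r0_value < 0:
        raise ValueError(f"R0 must be a finite nonnegative number, got {r0_value!r}")
    if r0_value < 1.0 - THRESHOLD_EPS:
        return Persistence.EXTINCTION
    if r0_value > 1.0 + THRESHOLD_EPS:
        return Persistence.PERSISTENCE
    return Persistence.THRESHOLD


def coefficients(params: ModelParameters, S0: float, N: float) -> QuadraticCoefficients:
    """Evaluate the quadratic coefficients A, B, C.

    ``S0`` is the initial sedentary count and ``N`` the total population;
    only their ratio matters for R0 itself, but the coefficients are kept
    on the person^2-rate^2 scale they are defined on.
    """
    if not (math.isfinite(N) and N > 0):
        raise DegeneratePopulationError(f"N must be > 0, got {N!r}")
    if not (math.isfinite(S0) and 0 <= S0 <= N):
        raise ValueError(f"S0 must satisfy 0 <= S0 <= N, got S0={S0!r}, N={N!r}")
    p = params
    A = (
        N**2 * (p.alpha1 * p.delta1 + p.delta2 * (p.alpha2 + p.delta1))
        + N * S0 * (p.beta1 * (p.alpha1 + p.delta2) + p.beta2 * (p.alpha2 + p.delta1))
        + S0**2 * p.beta1 * p.beta2
    )
    B = S0 * (
        N * (p.alpha1 * p.k1 + p.delta1 * p.k2)
        + N * (p.alpha2 * (p.k2 + p.r2) + p.r1 * (p.alpha1 + p.delta2))
        + S0 * (p.beta1 * p.k2 + p.beta2 * p.r1)
    )
    C = (p.r1 * p.k2 - p.r2 * p.k1) * S0**2
    return QuadraticCoefficients(A=A, B=B, C=C)


def r0_closed_form(params: ModelParameters, S0: float, N: float) -> R0Result:
    """General closed-form R0: the larger root ``(B + sqrt(B^2-4AC)) / (2A)``.

    Raises
    ------
    DegenerateFormulaError
        If A = 0 (all of the recidivism/exchange products vanish); the
        general formula is undefined there and one of the special-case
        formulas must be used instead.
    FormulaDomainError
        If the discriminant is genuinely negative (beyond floating-point
        noise, which is clamped to zero).
    """
    coeffs = coefficients(params, S0, N)
    if coeffs.A == 0:
        raise DegenerateFormulaError(
            "leading coefficient A = 0: the general R0 formula is undefined; "
            "use r0_case1/r0_case2/r0_case3 for the matching parameter pattern"
        )
    disc = coeffs.B**2 - 4.0 * coeffs.A * coeffs.C
    if disc < 0:
        if abs(disc) <= _DISC_CLAMP_REL * max(1.0, coeffs.B**2):
            disc = 0.0
        else:
            raise FormulaDomainError(
                f"negative discriminant B^2 - 4AC = {disc!r} "
                f"(A={coeffs.A!r}, B={coeffs.B!r}, C={coeffs.C!r})"
            )
    value = (coeffs.B + math.sqrt(disc)) / (2.0 * coeffs.A)
    return R0Result(
        value=value,
        method=R0Method.CLOSED_FORM,
        classification=classify_persistence(value),
        coefficients=coeffs,
    )


def _require_zero(params: ModelParameters, names: tuple[str, ...], case: str) -> None:
    for name in names:
        if getattr(params, name) != 0:
            raise CaseMismatchError(
                f"{case} requires {name} = 0 exactly, got {getattr(params, name)!r}"
            )


def r0_case2(params: ModelParameters) -> R0Result:
    """Case 2 reduction: R0 = (k1 + r1) / beta1.

    Valid when sedentary and extremely active individuals do not interact
    and all spontaneous flows vanish:
    ``r2 = k2 = beta2 = gamma1 = gamma2 = delta1 = delta2 = 0``.
    """
    _require_zero(
        params,
        ("r2", "k2", "beta2", "gamma1", "gamma2", "delta1", "delta2"),
        "Case 2",
    )
    if params.beta1 == 0:
        raise ZeroDivisionError("Case 2 R0 = (k1 + r1)/beta1 requires beta1 > 0")
    value = (params.k1 + params.r1) / params.beta1
    return R0Result(
        value=value, method=R0Method.CASE2, classification=classify_persistence(value)
    )


def r0_case3(params: ModelParameters, S0: float, N: float) -> R0Result:
    """Case 3 reduction: R0 = (k1 + r1) p / (beta1 p + delta1), p = S0/N.

    Valid when sedentary and extremely active individuals do not interact,
    there is no spontaneous uptake, and the extremely active never
    spontaneously drop out: ``r2 = k2 = beta2 = gamma1 = gamma2 = delta2 = 0``.

    The result carries ``persistence_inequality``, the threshold condition
    in its printed product form ``(k1 + r1) p > beta1 p + delta1``, which is
    equivalent to ``k1 + r1 > beta1 + delta1/p`` for p > 0.
    """
    _require_zero(
        params, ("r2", "k2", "beta2", "gamma1", "gamma2", "delta2"), "Case 3"
    )
    if not (math.isfinite(N) and N > 0):
        raise DegeneratePopulationError(f"N must be > 0, got {N!r}")
    if not (0 <= S0 <= N):
        raise ValueError(f"S0 must satisfy 0 <= S0 <= N, got S0={S0!r}")
    frac = S0 / N
    denom = params.beta1 * frac + params.delta1
    if denom == 0:
        raise ZeroDivisionError(
            "Case 3 R0 denominator beta1*p + delta1 is zero; "
            "no recidivism pathway from E1 exists"
        )
    value = (params.k1 + params.r1) * frac / denom
    inequality = (params.k1 + params.r1) * frac > params.beta1 * frac + params.delta1
    return R0Result(
        value=value,
        method=R0Method.CASE3,
        classification=classify_persistence(value),
        persistence_inequality=inequality,
    )


def ngm_matrices(
    params: ModelParameters, S0: float, N: float
) -> tuple[np.ndarray, np.ndarray]:
    """Next-generation matrices (F, V) linearized at the activity-free state.

    With the active compartments (E1, E2) as the "infected" block and the
    sedentary fraction fixed at ``s = S0/N``:

    * F holds the creation of new active individuals out of the sedentary
      pool — the r1, r2, k1, k2 contact terms;
    * V holds removals back to S (beta, delta terms) and the exchange
      between active compartments (alpha terms).
    """
    s = S0 / N
    F = np.array(
        [
            [params.r1 * s, params.r2 * s],
            [params.k1 * s, params.k2 * s],
        ]
    )
    V = np.array(
        [
            [params.beta1 * s + params.alpha2 + params.delta1, -params.alpha1],
            [-params.alpha2, params.alpha1 + params.beta2 * s + params.delta2],
        ]
    )
    return F, V


def r0_ngm(params: ModelParameters, S0: float, N: float) -> R0Result:
    """Numerical R0 as the spectral radius of ``F @ inv(V)``.

    Requires ``gamma1 = gamma2 = 0``: with spontaneous uptake the
    all-sedentary state is not an equilibrium and the next-generation
    construction has no disease-free equilibrium to linearize at. The
    linearization uses the sedentary fraction ``S0/N``, matching the way
    ``S0`` enters the closed form.
    """
    if params.gamma1 != 0 or params.gamma2 != 0:
        raise DfeNotEquilibriumError(
            "r0_ngm requires gamma1 = gamma2 = 0: spontaneous uptake makes "
            "the all-sedentary state a non-equilibrium "
            f"(gamma1={params.gamma1!r}, gamma2={params.gamma2!r})"
        )
    if not (math.isfinite(N) and N > 0):
        raise DegeneratePopulationError(f"N must be > 0, got {N!r}")
    if not (0 <= S0 <= N):
        raise ValueError(f"S0 must satisfy 0 <= S0 <= N, got S0={S0!r}")
    F, V = ngm_matrices(params, S0, N)
    if abs(np.linalg.det(V)) == 0:
        raise NonInvertibleTransitionError(
            "transition matrix V is singular; no removal pathway exists for "
            "some active compartment"
        )
    K = F @ np.linalg.inv(V)
    value = float(max(abs(np.linalg.eigvals(K))))
    return R0Result(
        value=value, method=R0Method.NGM, classification=classify_persistence(value)
    )
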