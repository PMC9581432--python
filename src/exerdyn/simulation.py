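"""Forward integration of scenarios and plateau/extinction detection.

The integrator is SciPy's LSODA (adaptive step with automatic switching to a
stiff BDF method), run at tight tolerances so that conservation of the total
population and refinement stability hold to well below the reporting
precision. Any adaptive integrator meeting the refinement-stability
property would do; LSODA is chosen for its stiff fallback.

"Plateau" and "extinction" are operationalized rather than read off a
figure: a trajectory has *settled* when the largest time-derivative over the
trailing fifth of the horizon falls below ``rate_eps * N``, and a
compartment is *extinct* when its final fraction of the population falls
below ``extinct_eps``. Preset runs double the horizon (up to a cap) until
the settling criterion is met, so reported plateaus are genuine steady
levels, not snapshots of a slow transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidStateError
from .model import ModelParameters, PopulationState, Scenario, rhs_raw

#: Default solver tolerances.
DEFAULT_REL_TOL = 1e-8
DEFAULT_ABS_TOL = 1e-10

#: Plateau-detection defaults: rate criterion (week^-1, relative to N),
#: extinction threshold (fraction of N), trailing-window width (fraction
#: of the horizon).
DEFAULT_RATE_EPS = 1e-8
DEFAULT_EXTINCT_EPS = 1e-3
DEFAULT_WINDOW_FRAC = 0.2

#: Preset horizons: start at 500 weeks, double until settled, cap at 8000.
DEFAULT_HORIZON = 500.0
MAX_HORIZON = 8000.0

#: Default population size for fraction-specified initial conditions. The
#: dynamics depend only on the fractions because every nonlinear term is
#: scaled by N.
DEFAULT_POPULATION = 1000.0

#: Trajectory conservation tolerance, relative to N(0).
CONSERVATION_RTOL = 1e-6

COMPARTMENTS = ("S", "E1", "E2")


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed solution of a scenario.

    ``times`` starts at 0 and is strictly increasing; ``S``, ``E1``, ``E2``
    are aligned arrays of compartment sizes (persons).
    """

    scenario: Scenario
    times: np.ndarray
    S: np.ndarray
    E1: np.ndarray
    E2: np.ndarray

    @property
    def states(self) -> list[PopulationState]:
        """The trajectory as a list of validated states."""
        return [
            PopulationState(t=float(t), S=float(s), E1=float(e1), E2=float(e2))
            for t, s, e1, e2 in zip(self.times, self.S, self.E1, self.E2)
        ]

    @property
    def final_state(self) -> PopulationState:
        return PopulationState(
            t=float(self.times[-1]),
            S=float(self.S[-1]),
            E1=float(self.E1[-1]),
            E2=float(self.E2[-1]),
        )

    def as_dataframe(self) -> pd.DataFrame:
        """Columns ``t, S, E1, E2, N``, one row per output point."""
        return pd.DataFrame(
            {
                "t": self.times,
                "S": self.S,
                "E1": self.E1,
                "E2": self.E2,
                "N": self.S + self.E1 + self.E2,
            }
        )


@dataclass(frozen=True)
class PlateauReport:
    """Outcome summary of a trajectory.

    ``settled`` — trailing-window rate criterion met;
    ``final_fractions`` — (S, E1, E2)/N at the last time point;
    ``extinct`` — compartment labels whose final fraction is below the
    extinction threshold.
    """

    settled: bool
    final_fractions: tuple[float, float, float]
    extinct: frozenset[str] = field(default_factory=frozenset)


def integrate(
    scenario: Scenario,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    n_output_points: int = 1001,
) -> Trajectory:
    """Integrate a scenario over [0, horizon].

    Output is sampled at ``n_output_points`` evenly spaced times. Tiny
    negative excursions (within the solver's absolute tolerance) are clamped
    to zero; anything larger, or a conservation violation beyond
    ``1e-6 * N(0)``, raises :class:`IntegrationError`.
    """
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("solver tolerances must be > 0")
    if n_output_points < 2:
        raise ValueError("n_output_points must be >= 2")

    params = scenario.params
    y0 = [scenario.initial.S, scenario.initial.E1, scenario.initial.E2]
    n0 = sum(y0)
    t_eval = np.linspace(0.0, scenario.horizon, n_output_points)

    sol = solve_ivp(
        lambda t, y: rhs_raw(params, y[0], y[1], y[2]),
        (0.0, scenario.horizon),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        failed_at = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(
            f"integration failed at t = {failed_at:.6g} weeks: {sol.message}",
            failure_time=failed_at,
        )

    y = sol.y
    # clamp excursions the solver is entitled to (order abs_tol); anything
    # worse indicates a genuine failure, not roundoff
    clamp_floor = -max(abs_tol, 1e-9 * n0)
    if y.min() < clamp_floor:
        raise IntegrationError(
            f"compartment went negative beyond tolerance: min = {y.min():.3e}",
            failure_time=float(sol.t[int(np.argmin(y.min(axis=0)))]),
        )
    y = np.clip(y, 0.0, None)

    drift = np.max(np.abs(y.sum(axis=0) - n0))
    if drift > CONSERVATION_RTOL * n0:
        raise IntegrationError(
            f"population conservation violated: max drift {drift:.3e} persons "
            f"exceeds {CONSERVATION_RTOL:.0e} * N(0)"
        )
    return Trajectory(scenario=scenario, times=sol.t, S=y[0], E1=y[1], E2=y[2])


def detect_plateau(
    traj: Trajectory,
    rate_eps: float = DEFAULT_RATE_EPS,
    extinct_eps: float = DEFAULT_EXTINCT_EPS,
    window_frac: float = DEFAULT_WINDOW_FRAC,
) -> PlateauReport:
    """Classify the tail of a trajectory as settled/unsettled and extinct.

    ``settled`` is true iff the largest right-hand-side magnitude over the
    trailing ``window_frac`` of the horizon is below ``rate_eps * N``.
    """
    if traj.times.size == 0:
        raise InvalidStateError("trajectory is empty")
    if not (0 < window_frac < 1):
        raise ValueError(f"window_frac must be in (0, 1), got {window_frac!r}")

    params = traj.scenario.params
    t_end = traj.times[-1]
    window_start = t_end - window_frac * (t_end - traj.times[0])
    in_window = traj.times >= window_start
    n0 = traj.S[0] + traj.E1[0] + traj.E2[0]

    max_rate = 0.0
    for s, e1, e2 in zip(traj.S[in_window], traj.E1[in_window], traj.E2[in_window]):
        max_rate = max(max_rate, *map(abs, rhs_raw(params, s, e1, e2)))
    settled = bool(max_rate < rate_eps * n0)

    final = traj.final_state
    fractions = final.fractions()
    extinct = frozenset(
        name for name, frac in zip(COMPARTMENTS, fractions) if frac < extinct_eps
    )
    return PlateauReport(settled=settled, final_fractions=fractions, extinct=extinct)


def simulate_to_plateau(
    scenario: Scenario,
    rel_tol: float = DEFAULT_REL_TOL,
    abs_tol: float = DEFAULT_ABS_TOL,
    n_output_points: int = 1001,
    rate_eps: float = DEFAULT_RATE_EPS,
    extinct_eps: float = DEFAULT_EXTINCT_EPS,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    max_horizon: float = MAX_HORIZON,
) -> tuple[Trajectory, PlateauReport]:
    """Integrate, doubling the horizon until settled or ``max_horizon``.

    Returns the last trajectory and its plateau report; the report's
    ``settled`` flag is False if the cap was reached without settling.
    """
    import dataclasses

    current = scenario
    while True:
        traj = integrate(current, rel_tol=rel_tol, abs_tol=abs_tol,
                         n_output_points=n_output_points)
        report = detect_plateau(traj, rate_eps=rate_eps,
                                extinct_eps=extinct_eps, window_frac=window_frac)
        if report.settled or current.horizon * 2 > max_horizon:
            return traj, report
        current = dataclasses.replace(current, horizon=current.horizon * 2)


def _fraction_scenario(
    params: ModelParameters,
    fractions: tuple[float, float, float],
    label: str,
    population: float = DEFAULT_POPULATION,
    horizon: float = DEFAULT_HORIZON,
) -> Scenario:
    fS, fE1, fE2 = fractions
    if not math.isclose(fS + fE1 + fE2, 1.0, rel_tol=0, abs_tol=1e-6):
        raise InvalidStateError(
            f"initial fractions must sum to 1 within 1e-6, got {fractions!r}"
        )
    initial = PopulationState(
        t=0.0, S=fS * population, E1=fE1 * population, E2=fE2 * population
    )
    return Scenario(params=params, initial=initial, horizon=horizon, label=label)


def _preset_scenarios() -> dict[str, Scenario]:
    # Persistence scenario: social uptake (k1 + r1) dominates moderate-active
    # recidivism beta1, so R0 = 0.017/0.0022 > 1 and sedentariness dies out.
    fig3a = _fraction_scenario(
        ModelParameters(k1=0.002, r1=0.015, beta1=0.0022, alpha1=0.005, alpha2=0.005),
        (0.5, 0.3, 0.2),
        label="fig3a",
    )
    # Same setup with recidivism raised to beta1 = 0.035: R0 < 1 and the
    # active compartments go extinct.
    fig3b = _fraction_scenario(
        ModelParameters(k1=0.002, r1=0.015, beta1=0.035, alpha1=0.005, alpha2=0.005),
        (0.5, 0.3, 0.2),
        label="fig3b",
    )
    # One-at-a-time sensitivity baseline: every rate constant at 0.001,
    # population split evenly across the three compartments.
    baseline = _fraction_scenario(
        ModelParameters(**{name: 0.001 for name in ModelParameters().as_dict()}),
        (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0),
        label="sensitivity_baseline",
    )
    return {"fig3a": fig3a, "fig3b": fig3b, "sensitivity_baseline": baseline}


PRESET_NAMES = ("fig3a", "fig3b", "sensitivity_baseline")


def preset_scenario(name: str) -> Scenario:
    """Return one of the built-in scenarios by name."""
    presets = _preset_scenarios()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    return presets[name]


def run_preset(name: str) -> tuple[Scenario, Trajectory, PlateauReport]:
    """Run a built-in scenario to plateau."""
    scenario = preset_scenario(name)
    traj, report = simulate_to_plateau(scenario)
    return scenario, traj, report
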