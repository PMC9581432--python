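"""One-at-a-time (OAT) sensitivity of the sedentary plateau.

The protocol: fix every rate constant at a common baseline (0.001 week^-1,
with the population split evenly across the three compartments), vary one
parameter — or a named group in lockstep — over a multiplicative grid, run
each modified scenario to plateau, and record the sedentary fraction at
the plateau.

The default grid multiplies the baseline by {1, 2, 5, 10}; the magnitudes
are a package choice made to give unambiguous response directions, since
the protocol itself only fixes the baseline. The qualitative picture this
produces: the uptake parameters (r1, r2, k1, k2, gamma1, gamma2) lower the
sedentary plateau, the recidivism parameters (beta1, beta2, delta1, delta2)
raise it, and the inter-exerciser exchange rates (alpha1, alpha2) leave it
unchanged — at a fully symmetric baseline the sedentary dynamics depend on
E1 + E2 only, never on how activity is split between E1 and E2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import UndefinedChangeError
from .model import PARAMETER_NAMES, Scenario
from .simulation import preset_scenario, simulate_to_plateau

logger = logging.getLogger(__name__)

#: Plateau responses smaller than this (in absolute sedentary fraction)
#: are reported as flat.
FLATNESS_BAND = 1e-6

DEFAULT_FACTORS = (1.0, 2.0, 5.0, 10.0)


class Direction(str, Enum):
    DECREASING = "decreasing"
    INCREASING = "increasing"
    FLAT = "flat"


@dataclass(frozen=True)
class SweepResult:
    """Outcome of a one-at-a-time sweep.

    ``plateau_S`` holds the sedentary final fraction at each grid value;
    an entry is NaN if that run did not settle within the maximum horizon
    (reported with a warning, not a failure). ``direction`` compares the
    first and last settled grid points against the flatness band.
    """

    parameter: str
    grid: tuple[float, ...]
    plateau_S: tuple[float, ...]
    direction: Direction


def _direction(first: float, last: float, band: float = FLATNESS_BAND) -> Direction:
    if math.isnan(first) or math.isnan(last):
        return Direction.FLAT
    delta = last - first
    if delta > band:
        return Direction.INCREASING
    if delta < -band:
        return Direction.DECREASING
    return Direction.FLAT


def oat_sweep(
    baseline: Scenario,
    parameter: str | Iterable[str],
    grid: Sequence[float],
) -> SweepResult:
    """Vary one rate constant (or several in lockstep) over a value grid.

    Each grid value replaces the named parameter(s); all other parameters
    stay at their baseline values. Each modified scenario is run to plateau
    and the sedentary final fraction recorded.
    """
    names = (parameter,) if isinstance(parameter, str) else tuple(parameter)
    if not names:
        raise ValueError("at least one parameter name is required")
    for name in names:
        if name not in PARAMETER_NAMES:
            raise KeyError(
                f"unknown parameter {name!r}; expected one of {PARAMETER_NAMES}"
            )
    grid = tuple(float(v) for v in grid)
    if any(v < 0 for v in grid):
        raise ValueError("grid values must be >= 0")
    if list(grid) != sorted(set(grid)):
        raise ValueError("grid must be strictly increasing")

    plateau_S: list[float] = []
    for value in grid:
        params = baseline.params.replace(**{name: value for name in names})
        scenario = Scenario(
            params=params,
            initial=baseline.initial,
            horizon=baseline.horizon,
            label=f"{baseline.label}:{'+'.join(names)}={value:g}",
        )
        _, report = simulate_to_plateau(scenario)
        if not report.settled:
            logger.warning(
                "sweep point %s did not settle within the maximum horizon; "
                "recording plateau as missing", scenario.label,
            )
            plateau_S.append(math.nan)
        else:
            plateau_S.append(report.final_fractions[0])

    settled_points = [v for v in plateau_S if not math.isnan(v)]
    if settled_points:
        direction = _direction(settled_points[0], settled_points[-1])
    else:
        direction = Direction.FLAT
    return SweepResult(
        parameter="+".join(names),
        grid=grid,
        plateau_S=tuple(plateau_S),
        direction=direction,
    )


def default_grid(baseline_value: float, factors: Sequence[float] = DEFAULT_FACTORS) -> tuple[float, ...]:
    """Multiplicative sweep grid ``factors * baseline_value``."""
    if baseline_value < 0:
        raise ValueError("baseline value must be >= 0")
    return tuple(f * baseline_value for f in factors)


def sweep_from_baseline(
    parameter: str | Iterable[str],
    factors: Sequence[float] = DEFAULT_FACTORS,
    baseline: Scenario | None = None,
) -> SweepResult:
    """Convenience wrapper: OAT sweep from the standard baseline scenario.

    ``factors`` scale the baseline value of the (first-named) parameter.
    """
    if baseline is None:
        baseline = preset_scenario("sensitivity_baseline")
    names = (parameter,) if isinstance(parameter, str) else tuple(parameter)
    base_value = getattr(baseline.params, names[0])
    return oat_sweep(baseline, names, default_grid(base_value, factors))


def plateau_change_pct(baseline_plateau_S: float, varied_plateau_S: float) -> float:
    """Signed percent change of the sedentary plateau relative to baseline."""
    if baseline_plateau_S == 0:
        raise UndefinedChangeError(
            "percent change undefined: baseline sedentary plateau is zero"
        )
    return 100.0 * (varied_plateau_S - baseline_plateau_S) / baseline_plateau_S
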