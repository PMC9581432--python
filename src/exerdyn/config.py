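"""Run configuration: flat YAML files mapping names to scalars.

A config file is a single flat mapping. Rate constants use the transliterated
symbol names (``gamma1`` for γ1 and so on); missing rates default to 0 with a
logged notice. Run settings carry the simulation defaults.

Example::

    # persistence scenario
    k1: 0.002
    r1: 0.015
    beta1: 0.0022
    alpha1: 0.005
    alpha2: 0.005
    initial_fractions: [0.5, 0.3, 0.2]
    population_size: 1000
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .model import PARAMETER_NAMES, ModelParameters, PopulationState, Scenario
from . import simulation as _sim

logger = logging.getLogger(__name__)

_RUN_KEYS = (
    "initial_fractions",
    "population_size",
    "horizon_weeks",
    "rel_tol",
    "abs_tol",
    "rate_eps",
    "extinct_eps",
    "window_frac",
    "seed",
    "label",
)
KNOWN_KEYS = frozenset(PARAMETER_NAMES) | frozenset(_RUN_KEYS)


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: parameters plus run settings."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    initial_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    population_size: float = _sim.DEFAULT_POPULATION
    horizon_weeks: float = _sim.DEFAULT_HORIZON
    rel_tol: float = _sim.DEFAULT_REL_TOL
    abs_tol: float = _sim.DEFAULT_ABS_TOL
    rate_eps: float = _sim.DEFAULT_RATE_EPS
    extinct_eps: float = _sim.DEFAULT_EXTINCT_EPS
    window_frac: float = _sim.DEFAULT_WINDOW_FRAC
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        fr = self.initial_fractions
        if len(fr) != 3 or any(not (0 <= f <= 1) for f in fr):
            raise ConfigError(
                f"initial_fractions must be three values in [0, 1], got {fr!r}"
            )
        if not math.isclose(sum(fr), 1.0, rel_tol=0, abs_tol=1e-6):
            raise ConfigError(
                f"initial_fractions must sum to 1 within 1e-6, got sum = {sum(fr)!r}"
            )
        if self.population_size <= 0:
            raise ConfigError("population_size must be > 0")
        if self.horizon_weeks <= 0:
            raise ConfigError("horizon_weeks must be > 0")
        for key in ("rel_tol", "abs_tol", "rate_eps", "extinct_eps"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be > 0")
        if not (0 < self.window_frac < 1):
            raise ConfigError("window_frac must be in (0, 1)")

    def to_scenario(self) -> Scenario:
        fS, fE1, fE2 = self.initial_fractions
        n = self.population_size
        return Scenario(
            params=self.parameters,
            initial=PopulationState(t=0.0, S=fS * n, E1=fE1 * n, E2=fE2 * n),
            horizon=self.horizon_weeks,
            label=self.label,
        )

    def to_dict(self) -> dict:
        """Flat mapping suitable for round-tripping through a config file."""
        out: dict = dict(self.parameters.as_dict())
        out["initial_fractions"] = list(self.initial_fractions)
        out["population_size"] = self.population_size
        out["horizon_weeks"] = self.horizon_weeks
        out["rel_tol"] = self.rel_tol
        out["abs_tol"] = self.abs_tol
        out["rate_eps"] = self.rate_eps
        out["extinct_eps"] = self.extinct_eps
        out["window_frac"] = self.window_frac
        out["seed"] = self.seed
        out["label"] = self.label
        return out


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat YAML config file.

    Unknown keys are an error (listed in the message); missing rate
    constants default to 0 with a logged notice.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(
            f"config file {path} must contain a flat key-value mapping, "
            f"got {type(raw).__name__}"
        )

    unknown = sorted(set(raw) - KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys in {path}: {', '.join(unknown)}")

    missing_rates = [name for name in PARAMETER_NAMES if name not in raw]
    if missing_rates:
        logger.info(
            "config %s: rate constants defaulting to 0: %s",
            path, ", ".join(missing_rates),
        )
    try:
        params = ModelParameters(
            **{name: raw[name] for name in PARAMETER_NAMES if name in raw}
        )
    except ValueError as exc:
        raise ConfigError(f"invalid rate constant in {path}: {exc}") from exc

    kwargs: dict = {"parameters": params}
    for key in _RUN_KEYS:
        if key in raw:
            value = raw[key]
            if key == "initial_fractions":
                value = tuple(float(v) for v in value)
            kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back out; ``load_config`` round-trips it losslessly."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=None)
    )
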