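"""TOML run configuration with protocol defaults.

The defaults encode the chamber protocol: pre-breakfast baseline window
0715-0745, morning 0800-1200, waking 0800-2300 (two-meal variant
1200-2300), sleep 2300-0700, integration grids half-width 0-30 min and lag
-20..+20 min, Weir coefficients, and a 2-min EE advance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import tomllib
from dataclasses import dataclass, field

from .estimators import MORNING, PRE_BREAKFAST, SLEEP, WAKING, WAKING_TWO_MEAL
from .session import (
    Period,
    WEIR_NITROGEN_COEF,
    WEIR_VCO2_COEF,
    WEIR_VO2_COEF,
)
from .simulate import DEFAULT_MEALS, MealSpec, SimulationParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "IntegrationConfig", "CalorimetryConfig", "load_config"]

# Search ranges the method was validated over; wider grids are accepted
# with a warning.
VALIDATED_HALF_WIDTH = (0, 30)
VALIDATED_LAG = (-20, 20)


class ConfigError(ValueError):
    """Malformed or out-of-contract configuration."""


@dataclass
class IntegrationConfig:
    half_width: tuple = VALIDATED_HALF_WIDTH
    lag: tuple = VALIDATED_LAG
    statistic: str = "mean"

    @property
    def half_widths(self):
        return tuple(range(self.half_width[0], self.half_width[1] + 1))

    @property
    def lags(self):
        return tuple(range(self.lag[0], self.lag[1] + 1))


@dataclass
class CalorimetryConfig:
    vo2_coef: float = WEIR_VO2_COEF
    vco2_coef: float = WEIR_VCO2_COEF
    nitrogen_coef: float = WEIR_NITROGEN_COEF
    advance_min: int = 2

    @property
    def coefficients(self):
        return (self.vo2_coef, self.vco2_coef, self.nitrogen_coef)


def default_periods() -> dict:
    return {
        p.name: p
        for p in (PRE_BREAKFAST, MORNING, WAKING, WAKING_TWO_MEAL, SLEEP)
    }


@dataclass
class RunConfig:
    periods: dict = field(default_factory=default_periods)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    calorimetry: CalorimetryConfig = field(default_factory=CalorimetryConfig)
    simulate: SimulationParams = field(default_factory=SimulationParams)

    def sha(self) -> str:
        """Short content hash for output provenance headers."""
        text = repr(
            (
                sorted(self.periods.items()),
                self.integration,
                self.calorimetry,
                self.simulate,
            )
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _apply_section(obj, table: dict, section: str):
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in table.items():
        if key not in names:
            raise ConfigError(f"unknown key [{section}].{key}")
        if isinstance(value, list):
            value = tuple(value)
        setattr(obj, key, value)
    return obj


def _parse_meals(items) -> tuple:
    meals = []
    for item in items:
        allowed = {f.name for f in dataclasses.fields(MealSpec)}
        bad = set(item) - allowed
        if bad:
            raise ConfigError(f"unknown meal key(s): {sorted(bad)}")
        meals.append(MealSpec(**item))
    return tuple(meals)


def load_config(path=None) -> RunConfig:
    """Load a TOML config, merged over defaults; unknown keys are errors."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {"periods", "integration", "calorimetry", "simulate"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    for name, spec in data.get("periods", {}).items():
        if not isinstance(spec, dict) or set(spec) - {"start", "end"}:
            raise ConfigError(
                f"period {name!r} must be a table with keys start, end"
            )
        cfg.periods[name] = Period(spec["start"], spec["end"], name)

    if "integration" in data:
        _apply_section(cfg.integration, data["integration"], "integration")
        lo, hi = cfg.integration.half_width
        if lo < 0:
            raise ConfigError("half_width grid must be non-negative")
        if hi > VALIDATED_HALF_WIDTH[1]:
            logger.warning(
                "half_width grid max %d exceeds the validated range %s",
                hi, VALIDATED_HALF_WIDTH,
            )
        if (cfg.integration.lag[0] < VALIDATED_LAG[0]
                or cfg.integration.lag[1] > VALIDATED_LAG[1]):
            logger.warning(
                "lag grid %s exceeds the validated range %s",
                cfg.integration.lag, VALIDATED_LAG,
            )
        if cfg.integration.statistic not in ("mean", "sum"):
            raise ConfigError(
                f"integration.statistic must be mean|sum, "
                f"got {cfg.integration.statistic!r}"
            )

    if "calorimetry" in data:
        _apply_section(cfg.calorimetry, data["calorimetry"], "calorimetry")
        if cfg.calorimetry.advance_min < 0:
            raise ConfigError("advance_min must be >= 0")

    if "simulate" in data:
        table = dict(data["simulate"])
        meals = table.pop("meals", None)
        sim = dataclasses.asdict(cfg.simulate)
        sim.pop("meals")
        allowed = set(sim)
        bad = set(table) - allowed
        if bad:
            raise ConfigError(f"unknown key(s) in [simulate]: {sorted(bad)}")
        for key in ("burst_duration_range",):
            if key in table:
                table[key] = tuple(table[key])
        kwargs = {**sim, **table}
        kwargs["meals"] = (
            _parse_meals(meals) if meals is not None else cfg.simulate.meals
        )
        cfg.simulate = SimulationParams(**kwargs)

    for key, value in sorted(_flatten(cfg).items()):
        logger.info("config %s = %s", key, value)
    return cfg


def _flatten(cfg: RunConfig) -> dict:
    out = {}
    for name, p in cfg.periods.items():
        out[f"periods.{name}"] = f"{p.start}-{p.end}"
    for f in dataclasses.fields(cfg.integration):
        out[f"integration.{f.name}"] = getattr(cfg.integration, f.name)
    for f in dataclasses.fields(cfg.calorimetry):
        out[f"calorimetry.{f.name}"] = getattr(cfg.calorimetry, f.name)
    for f in dataclasses.fields(cfg.simulate):
        out[f"simulate.{f.name}"] = getattr(cfg.simulate, f.name)
    return out
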