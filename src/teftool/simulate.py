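"""Synthetic 33-h chamber sessions with known latent components.

Emits a minute-resolution session whose EE is an additive mixture of a
circadian basal curve (with a sleep dip), per-meal thermic responses
(gamma-shaped), an activity-driven NEAT component built with a known
integration kernel, and Gaussian noise — together with the exact component
series, so estimator accuracy can be measured against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .neat import IntegrationSpec, integrate_activity
from .session import CalorimetrySession, MealEvent, Period, parse_clock

logger = logging.getLogger(__name__)

__all__ = [
    "MealSpec",
    "SimulationParams",
    "GroundTruth",
    "simulate_session",
    "without_meal",
    "recovery_experiment",
]

SLEEP_PERIOD = Period("23:00", "07:00", "sleep")


@dataclass(frozen=True)
class MealSpec:
    """A simulated meal and the shape of its thermic response."""

    time: str
    energy_kcal: float
    tef_fraction: float
    label: str = ""
    response_shape: float = 2.0
    response_scale: float = 60.0
    response_support_min: int = 360

    def __post_init__(self):
        parse_clock(self.time)
        if not 0.0 <= self.tef_fraction <= 0.25:
            raise ValueError(
                f"tef_fraction must be in [0, 0.25], got {self.tef_fraction}"
            )
        if self.energy_kcal <= 0:
            raise ValueError("meal energy must be > 0 kcal")
        if self.response_shape <= 0 or self.response_scale <= 0:
            raise ValueError("response shape/scale must be > 0")


# Defaults give roughly: 24-h EE ~1870 kcal, 24-h mean activity ~3500
# counts/min, sleep activity ~2250 counts/min, NEAT ~5-15% of waking EE.
DEFAULT_MEALS = (
    MealSpec("08:00", 689.0, 0.054, "breakfast"),
    MealSpec("12:00", 761.0, 0.057, "lunch"),
    MealSpec("19:00", 741.0, 0.060, "dinner"),
)


@dataclass(frozen=True)
class SimulationParams:
    """All simulator knobs; every random draw is reproducible from ``seed``."""

    basal_kcal_min: float = 1.15
    sleep_dip_fraction: float = 0.12
    circadian_amplitude: float = 0.02
    meals: tuple = DEFAULT_MEALS
    neat_slope: float = 8e-5
    neat_kernel_half_width: int = 7
    neat_kernel_lag: int = 0
    activity_base: float = 3450.0
    activity_jitter_sd: float = 120.0
    sleep_activity: float = 2250.0
    sleep_jitter_sd: float = 15.0
    burst_rate: float = 6.0            # bursts per waking hour
    burst_magnitude: float = 2500.0    # counts/min, jittered per burst
    burst_duration_range: tuple = (2, 8)
    noise_sd: float = 0.05
    noise_ar1_rho: float = 0.0
    floor_kcal_min: float = 0.05
    start_clock: str = "22:00"
    duration_min: int = 33 * 60
    start_date: str = "2000-01-01"
    condition: str = "three-meal"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "meals", tuple(self.meals))
        for name in (
            "basal_kcal_min", "sleep_dip_fraction", "circadian_amplitude",
            "neat_slope", "activity_base", "activity_jitter_sd",
            "sleep_activity", "sleep_jitter_sd", "burst_rate",
            "burst_magnitude", "noise_sd", "floor_kcal_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.sleep_dip_fraction < 1.0:
            raise ValueError("sleep_dip_fraction must be in [0, 1)")
        if not 0.0 <= self.noise_ar1_rho < 1.0:
            raise ValueError("noise_ar1_rho must be in [0, 1)")
        parse_clock(self.start_clock)
        if self.duration_min < 60:
            raise ValueError("duration_min must be >= 60")


@dataclass
class GroundTruth:
    """Latent component series; ``basal+tef+neat+noise`` equals the EE."""

    basal: np.ndarray
    tef: np.ndarray
    neat: np.ndarray
    noise: np.ndarray
    true_tef_fraction: dict
    neat_share_waking: float
    floor_events: int = 0


def _sleep_mask(minutes_of_day: np.ndarray) -> np.ndarray:
    lo, hi = parse_clock(SLEEP_PERIOD.start), parse_clock(SLEEP_PERIOD.end)
    return (minutes_of_day >= lo) | (minutes_of_day < hi)


def _tef_component(n, timestamps, meals) -> np.ndarray:
    minutes_of_day = (timestamps.hour * 60 + timestamps.minute).to_numpy()
    tef = np.zeros(n)
    for meal in meals:
        hits = np.nonzero(minutes_of_day == parse_clock(meal.time))[0]
        if hits.size == 0:
            raise ValueError(f"meal {meal.time} outside the session span")
        i0 = int(hits[0])
        support = min(meal.response_support_min, n - i0)
        offsets = np.arange(support) + 0.5
        pdf = stats.gamma.pdf(
            offsets, a=meal.response_shape, scale=meal.response_scale
        )
        mass = meal.tef_fraction * meal.energy_kcal
        # renormalize so the truncated, discretized response carries the
        # exact TEF mass
        tef[i0:i0 + support] += mass * pdf / pdf.sum()
    return tef


def simulate_session(params: SimulationParams, seed: int | None = None):
    """Generate one chamber stay; returns ``(CalorimetrySession, GroundTruth)``.

    Component randomness uses independent child streams of the seed, so a
    variant with a meal removed (fasted condition) shares the identical
    activity and noise realizations.
    """
    seed = params.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng_burst, rng_jitter, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    start = pd.Timestamp(f"{params.start_date} {params.start_clock}")
    timestamps = pd.date_range(start, periods=params.duration_min, freq="1min")
    n = len(timestamps)
    minutes_of_day = (timestamps.hour * 60 + timestamps.minute).to_numpy()
    sleep = _sleep_mask(minutes_of_day)

    # --- activity -----------------------------------------------------------
    activity = np.where(
        sleep,
        params.sleep_activity
        + params.sleep_jitter_sd * rng_jitter.standard_normal(n),
        params.activity_base
        + params.activity_jitter_sd * rng_jitter.standard_normal(n),
    )
    waking_idx = np.nonzero(~sleep)[0]
    n_bursts = rng_burst.poisson(params.burst_rate * waking_idx.size / 60.0)
    lo_d, hi_d = params.burst_duration_range
    for _ in range(n_bursts):
        i = int(rng_burst.choice(waking_idx))
        dur = int(rng_burst.integers(lo_d, hi_d + 1))
        mag = params.burst_magnitude * rng_burst.uniform(0.5, 1.5)
        j1 = min(i + dur, n)
        activity[i:j1] += mag * np.exp(-np.arange(j1 - i) / max(dur / 2.0, 1.0))
    activity = np.clip(activity, 0.0, None)

    # --- latent components --------------------------------------------------
    hours = minutes_of_day / 60.0
    basal = params.basal_kcal_min + params.circadian_amplitude * np.sin(
        2.0 * np.pi * (hours - 10.0) / 24.0
    )
    basal = basal * np.where(sleep, 1.0 - params.sleep_dip_fraction, 1.0)

    tef = _tef_component(n, timestamps, params.meals)

    kernel = IntegrationSpec(
        params.neat_kernel_half_width, params.neat_kernel_lag
    )
    aint = integrate_activity(activity, kernel)
    aint[~np.isfinite(aint)] = np.nanmin(aint)
    neat = params.neat_slope * (aint - np.nanmin(aint))

    if params.noise_sd > 0:
        white = rng_noise.standard_normal(n) * params.noise_sd
        if params.noise_ar1_rho > 0:
            rho = params.noise_ar1_rho
            noise = np.empty(n)
            noise[0] = white[0]
            for i in range(1, n):
                noise[i] = rho * noise[i - 1] + np.sqrt(1 - rho**2) * white[i]
        else:
            noise = white
    else:
        noise = np.zeros(n)

    ee = basal + tef + neat + noise
    floored = ee < params.floor_kcal_min
    floor_events = int(floored.sum())
    if floor_events:
        logger.warning("floored %d EE sample(s) at %.3f kcal/min",
                       floor_events, params.floor_kcal_min)
        ee = np.maximum(ee, params.floor_kcal_min)

    session = CalorimetrySession(
        timestamps=timestamps,
        ee=ee,
        activity=activity,
        meals=tuple(
            MealEvent(m.time, m.energy_kcal, m.label) for m in params.meals
        ),
        condition=params.condition,
    )
    waking_ee = ee[~sleep]
    truth = GroundTruth(
        basal=basal,
        tef=tef,
        neat=neat,
        noise=noise,
        true_tef_fraction={
            (m.label or m.time): m.tef_fraction for m in params.meals
        },
        neat_share_waking=float(neat[~sleep].sum() / waking_ee.sum()),
        floor_events=floor_events,
    )
    return session, truth


def without_meal(params: SimulationParams, label: str = "breakfast"):
    """Params for the fasted counterpart: drop one meal, keep all randomness."""
    kept = tuple(m for m in params.meals if (m.label or m.time) != label)
    if len(kept) == len(params.meals):
        raise ValueError(f"no meal labelled {label!r} to remove")
    return replace(params, meals=kept, condition=f"no-{label}")


# ---------------------------------------------------------------------------
# Recovery experiment

def recovery_experiment(
    params: SimulationParams,
    n_seeds: int,
    estimators=("delta_ee", "schutz_rmr", "schutz_smr", "neat_free"),
    *,
    base_seed: int = 0,
    meal_label: str = "breakfast",
    period=None,
    half_widths=None,
    lags=None,
    out=None,
):
    """Bias/RMSE of each estimator against the simulator's true TEF fraction.

    Simulates ``n_seeds`` subjects, applies each named estimator to the
    post-meal period (default: the 0800-1200 morning window), and compares
    the estimated TEF % with ``tef_fraction * 100``.  ``delta_ee`` re-runs
    each subject without the meal, sharing all other randomness.

    Returns ``(per_seed, summary)`` DataFrames; ``summary`` has one row per
    estimator with bias and RMSE in TEF percentage points.
    """
    from . import estimators as est
    from .neat import DEFAULT_HALF_WIDTHS, DEFAULT_LAGS

    half_widths = DEFAULT_HALF_WIDTHS if half_widths is None else half_widths
    lags = DEFAULT_LAGS if lags is None else lags
    if period is None:
        period = est.MORNING
    meal = next(
        m for m in params.meals if (m.label or m.time) == meal_label
    )
    truth_pct = meal.tef_fraction * 100.0

    rows = []
    for k in range(int(n_seeds)):
        seed = base_seed + k
        fed, _ = simulate_session(params, seed=seed)
        values = {}
        if "delta_ee" in estimators:
            fasted, _ = simulate_session(without_meal(params, meal_label),
                                         seed=seed)
            values["delta_ee"] = est.tef_delta_ee(
                fed, fasted, period, intake_kcal=meal.energy_kcal
            ).tef_percent
        if "schutz_rmr" in estimators:
            values["schutz_rmr"] = est.tef_schutz(
                fed, period, est.baseline_rmr(fed),
                intake_kcal=meal.energy_kcal, method="schutz_rmr",
            ).tef_percent
        if "schutz_smr" in estimators:
            values["schutz_smr"] = est.tef_schutz(
                fed, period, est.baseline_smr(fed),
                intake_kcal=meal.energy_kcal, method="schutz_smr",
            ).tef_percent
        if "neat_free" in estimators:
            values["neat_free"] = est.tef_original(
                fed, period, half_widths=half_widths, lags=lags,
                intake_kcal=meal.energy_kcal,
            ).tef_percent
        for name, value in values.items():
            rows.append(
                {"seed": seed, "estimator": name, "estimate_pct": value,
                 "truth_pct": truth_pct, "error_pct": value - truth_pct}
            )
    per_seed = pd.DataFrame(rows)
    summary = (
        per_seed.groupby("estimator")["error_pct"]
        .agg(bias="mean", rmse=lambda e: float(np.sqrt(np.mean(e**2))),
             n="size")
        .reset_index()
    )
    if out is not None:
        summary.to_csv(out, index=False)
    return per_seed, summary
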