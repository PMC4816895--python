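"""The four TEF calculation methods and their baselines.

Methods
-------
``delta_ee``
    Fed-minus-fasted energy expenditure over a clock-aligned period; the
    reference ("gold standard") approach.
``schutz_rmr`` / ``schutz_smr``
    Intercept of EE regressed on raw minute activity (EE at zero activity),
    minus the pre-breakfast resting or the sleeping metabolic rate, times
    the period duration.
``neat_free``
    Postprandial area of the NEAT-free EE series above the preprandial
    NEAT-free mean, using the lag-optimized integrated-activity model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neat import (
    DEFAULT_HALF_WIDTHS,
    DEFAULT_LAGS,
    NeatFit,
    ZeroActivityVarianceError,
    ee_free_series,
    fit_neat,
    neat_series,
    optimize_integration,
)
from .session import CalorimetrySession, Period, SessionError, format_clock

__all__ = [
    "PRE_BREAKFAST",
    "MORNING",
    "WAKING",
    "WAKING_TWO_MEAL",
    "SLEEP",
    "TefResult",
    "baseline_rmr",
    "baseline_smr",
    "preprandial_free_baseline",
    "ee0_intercept",
    "schutz_tef_kcal",
    "tef_schutz",
    "tef_delta_ee",
    "tef_original",
    "per_meal_tef",
]

# Canonical analysis windows of the chamber protocol.
PRE_BREAKFAST = Period("07:15", "07:45", "pre_breakfast")
MORNING = Period("08:00", "12:00", "morning")
WAKING = Period("08:00", "23:00", "waking")
WAKING_TWO_MEAL = Period("12:00", "23:00", "waking_two_meal")
SLEEP = Period("23:00", "07:00", "sleep")


@dataclass(frozen=True)
class TefResult:
    """One TEF estimate."""

    method: str
    period: Period
    minutes: int
    intake_kcal: float
    tef_kcal: float
    tef_percent: float
    baseline_kcal_min: float
    ee0_kcal_min: float | None = None
    degenerate: bool = False
    meal_label: str = ""
    condition: str = ""
    fit: NeatFit | None = field(default=None, compare=False, repr=False)

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "period": self.period.name or f"{self.period.start}-{self.period.end}",
            "start": self.period.start,
            "end": self.period.end,
            "minutes": self.minutes,
            "meal": self.meal_label,
            "condition": self.condition,
            "intake_kcal": self.intake_kcal,
            "tef_kcal": self.tef_kcal,
            "tef_percent": self.tef_percent,
            "baseline_kcal_min": self.baseline_kcal_min,
            "ee0_kcal_min": self.ee0_kcal_min,
            "degenerate": self.degenerate,
        }
        if self.fit is not None:
            row.update(
                fit_half_width=self.fit.spec.half_width,
                fit_lag=self.fit.spec.lag,
                fit_r=self.fit.r,
                fit_slope=self.fit.slope,
            )
        return row


def _result(method, period, intake_kcal, tef_kcal, baseline, **kw):
    if not intake_kcal > 0:
        raise SessionError(f"intake must be > 0 kcal, got {intake_kcal!r}")
    return TefResult(
        method=method,
        period=period,
        minutes=period.duration_minutes,
        intake_kcal=float(intake_kcal),
        tef_kcal=float(tef_kcal),
        tef_percent=float(100.0 * tef_kcal / intake_kcal),
        baseline_kcal_min=float(baseline),
        **kw,
    )


# ---------------------------------------------------------------------------
# Baselines

def baseline_rmr(session: CalorimetrySession, period: Period = PRE_BREAKFAST) -> float:
    """Resting metabolic rate: mean EE over the seated pre-breakfast window."""
    ee, _ = session.slice(period)
    return float(ee.mean())


def baseline_smr(session: CalorimetrySession, period: Period = SLEEP) -> float:
    """Sleeping metabolic rate: mean EE over the sleep window."""
    ee, _ = session.slice(period)
    return float(ee.mean())


def preprandial_free_baseline(
    session: CalorimetrySession,
    period: Period = PRE_BREAKFAST,
    half_widths=DEFAULT_HALF_WIDTHS,
    lags=DEFAULT_LAGS,
    statistic: str = "mean",
):
    """Mean NEAT-free EE over the pre-breakfast window.

    Fits the integrated-activity NEAT model on the window itself; with
    constant activity the model degrades to NEAT == 0 (flagged) and the
    baseline equals the plain RMR.  Returns ``(baseline, NeatFit)``.
    """
    sel = session.period_slice(period)
    try:
        spec, _ = optimize_integration(
            session.ee, session.activity, sel, half_widths, lags, statistic
        )
        fit = fit_neat(
            session.ee, session.activity, sel, spec, statistic,
            period_name=period.name or "preprandial",
        )
        if fit.degenerate:
            fit = NeatFit.null(period.name, statistic)
    except ZeroActivityVarianceError:
        fit = NeatFit.null(period.name, statistic)
    neat = neat_series(fit, session.activity)
    free = ee_free_series(session.ee, neat)
    return float(free[sel].mean()), fit


# ---------------------------------------------------------------------------
# Schutz-style intercept methods

def ee0_intercept(ee, x, sel=None) -> float:
    """OLS intercept of minute EE on raw minute activity over ``sel``."""
    ee = np.asarray(ee, dtype=float)
    x = np.asarray(x, dtype=float)
    if ee.shape != x.shape:
        raise ValueError("ee and activity must be aligned (equal length)")
    if sel is None:
        sel = slice(None)
    elif not isinstance(sel, slice):
        sel = slice(int(sel[0]), int(sel[1]))
    xs, ys = x[sel], ee[sel]
    if xs.size < 2 or np.ptp(xs) == 0.0:
        raise ZeroActivityVarianceError(
            "zero activity variance over the regression period"
        )
    xd = xs - xs.mean()
    slope = float(np.dot(xd, ys - ys.mean()) / np.dot(xd, xd))
    return float(ys.mean() - slope * xs.mean())


def schutz_tef_kcal(ee0: float, baseline: float, minutes: int) -> float:
    """TEF (kcal) as (EE at zero activity - baseline) over the period."""
    return (ee0 - baseline) * minutes


def tef_schutz(
    session: CalorimetrySession,
    period: Period,
    baseline_kcal_min: float,
    intake_kcal: float | None = None,
    method: str = "schutz_rmr",
) -> TefResult:
    """Intercept-above-baseline TEF over ``period``.

    ``baseline_kcal_min`` comes from :func:`baseline_rmr` (original method)
    or :func:`baseline_smr` (modified method).  Negative estimates are
    returned as-is with a warning; they are a documented failure mode of
    this method, not an error.
    """
    sel = session.period_slice(period)
    ee0 = ee0_intercept(session.ee, session.activity, sel)
    if intake_kcal is None:
        intake_kcal = _intake_in_period(session, period)
    tef_kcal = schutz_tef_kcal(ee0, baseline_kcal_min, period.duration_minutes)
    if tef_kcal < 0:
        warnings.warn(
            f"{method} returned a negative TEF ({tef_kcal:.1f} kcal)",
            stacklevel=2,
        )
    return _result(
        method, period, intake_kcal, tef_kcal, baseline_kcal_min,
        ee0_kcal_min=float(ee0), condition=session.condition,
    )


# ---------------------------------------------------------------------------
# Fed-minus-fasted reference method

def tef_delta_ee(
    fed: CalorimetrySession,
    fasted: CalorimetrySession,
    period: Period = MORNING,
    intake_kcal: float | None = None,
) -> TefResult:
    """TEF as the accumulated fed-minus-fasted EE difference over ``period``.

    The two sessions are aligned by wall clock; the default intake is the
    energy of meals present in the fed but not the fasted session within
    the period (i.e. the test meal).
    """
    sel_fed = fed.period_slice(period)
    sel_fas = fasted.period_slice(period)
    t_fed = fed.minutes_of_day[sel_fed]
    t_fas = fasted.minutes_of_day[sel_fas]
    if t_fed.size != t_fas.size or np.any(t_fed != t_fas):
        raise SessionError("fed and fasted sessions are not clock-aligned")
    if intake_kcal is None:
        intake_kcal = _intake_in_period(fed, period) - _intake_in_period(
            fasted, period, default=0.0
        )
        if intake_kcal <= 0:
            raise SessionError(
                "cannot infer the differential intake; pass intake_kcal"
            )
    diff = fed.ee[sel_fed] - fasted.ee[sel_fas]
    return _result(
        "delta_ee", period, intake_kcal, float(diff.sum()),
        float(fasted.ee[sel_fas].mean()), condition=fed.condition,
    )


# ---------------------------------------------------------------------------
# NEAT-free (original) method

def _intake_in_period(session, period: Period, default=None) -> float:
    sel = session.period_slice(period)
    clocks = set(session.minutes_of_day[sel].tolist())
    total = sum(
        m.energy_kcal for m in session.meals if m.minute_of_day in clocks
    )
    if total == 0:
        if default is not None:
            return default
        raise SessionError(
            f"no meals inside period {period.name or period.start}; "
            "pass intake_kcal explicitly"
        )
    return float(total)


def _fit_for_period(session, period, half_widths, lags, statistic):
    sel = session.period_slice(period)
    try:
        spec, _ = optimize_integration(
            session.ee, session.activity, sel, half_widths, lags, statistic
        )
        fit = fit_neat(
            session.ee, session.activity, sel, spec, statistic,
            period_name=period.name,
        )
        if fit.degenerate:
            return NeatFit.null(period.name, statistic)
        return fit
    except ZeroActivityVarianceError:
        warnings.warn(
            f"constant activity over {period.name or period.start}: "
            "falling back to NEAT == 0",
            stacklevel=3,
        )
        return NeatFit.null(period.name, statistic)


def tef_original(
    session: CalorimetrySession,
    period: Period = MORNING,
    pre_period: Period = PRE_BREAKFAST,
    *,
    half_widths=DEFAULT_HALF_WIDTHS,
    lags=DEFAULT_LAGS,
    statistic: str = "mean",
    intake_kcal: float | None = None,
    fit: NeatFit | None = None,
) -> TefResult:
    """NEAT-removal TEF: postprandial NEAT-free EE above the preprandial mean.

    Pipeline: (1) fit the integrated-activity NEAT model separately on the
    pre-breakfast window and on ``period`` (grid-searching half-width and
    lag each time); (2) remove NEAT from EE; (3) take the pre-breakfast
    NEAT-free mean as baseline; (4) accumulate the postprandial excess.
    A caller-supplied ``fit`` (e.g. the waking-period fit) skips step 1 for
    the postprandial model.
    """
    baseline, pre_fit = preprandial_free_baseline(
        session, pre_period, half_widths, lags, statistic
    )
    if fit is None:
        fit = _fit_for_period(session, period, half_widths, lags, statistic)
    sel = session.period_slice(period)
    free = ee_free_series(session.ee, neat_series(fit, session.activity))
    tef_kcal = float((free[sel] - baseline).sum())
    if intake_kcal is None:
        intake_kcal = _intake_in_period(session, period)
    return _result(
        "neat_free", period, intake_kcal, tef_kcal, baseline,
        degenerate=bool(fit.degenerate or pre_fit.degenerate),
        condition=session.condition, fit=fit,
    )


def per_meal_tef(
    session: CalorimetrySession,
    horizon_min: int = 240,
    *,
    fit_period: Period = WAKING,
    pre_period: Period = PRE_BREAKFAST,
    half_widths=DEFAULT_HALF_WIDTHS,
    lags=DEFAULT_LAGS,
    statistic: str = "mean",
    refit_per_meal: bool = False,
    per_meal_baseline: bool = False,
    baseline_window_min: int = 30,
) -> list[TefResult]:
    """NEAT-free TEF accumulated over ``horizon_min`` after each meal.

    By default one NEAT model is fitted on ``fit_period`` and reused for
    every meal, and the pre-breakfast NEAT-free mean is the baseline for
    all meals.  ``refit_per_meal`` refits the model on each meal window;
    ``per_meal_baseline`` instead uses the NEAT-free mean of the
    ``baseline_window_min`` minutes before each meal.
    """
    if not session.meals:
        raise SessionError("session has no meals")
    baseline, _ = preprandial_free_baseline(
        session, pre_period, half_widths, lags, statistic
    )
    shared_fit = None
    if not refit_per_meal:
        shared_fit = _fit_for_period(
            session, fit_period, half_widths, lags, statistic
        )
    results = []
    for meal in session.meals:
        start_min = meal.minute_of_day
        end_min = (start_min + int(horizon_min)) % 1440
        period = Period(
            format_clock(start_min), format_clock(end_min),
            name=f"post_{meal.label or meal.time}",
        )
        sel = session.period_slice(period)
        fit = shared_fit
        if fit is None:
            fit = _fit_for_period(session, period, half_widths, lags, statistic)
        free = ee_free_series(session.ee, neat_series(fit, session.activity))
        if per_meal_baseline:
            i0 = sel.start - int(baseline_window_min)
            if i0 < 0:
                raise SessionError(
                    f"no {baseline_window_min}-min preprandial window before "
                    f"{meal.label or meal.time}"
                )
            b = float(free[i0:sel.start].mean())
        else:
            b = baseline
        tef_kcal = float((free[sel] - b).sum())
        results.append(
            _result(
                "neat_free", period, meal.energy_kcal, tef_kcal, b,
                degenerate=bool(fit.degenerate), meal_label=meal.label,
                condition=session.condition, fit=fit,
            )
        )
    return results


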