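"""Decomposition of energy expenditure into a NEAT component and its remainder.

Implements the moving-window integration of accelerometer activity, the
exhaustive (half-width, lag) grid search maximizing the Pearson correlation
with energy expenditure, the linear NEAT model anchored at the period's
lowest integrated activity, and the construction of the NEAT-free EE series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntegrationSpec",
    "NeatFit",
    "ZeroActivityVarianceError",
    "integrate_activity",
    "optimize_integration",
    "fit_neat",
    "neat_series",
    "ee_free_series",
    "DEFAULT_HALF_WIDTHS",
    "DEFAULT_LAGS",
]

#: Default search grids: window half-width 0..30 min, lag -20..+20 min.
DEFAULT_HALF_WIDTHS = tuple(range(0, 31))
DEFAULT_LAGS = tuple(range(-20, 21))

#: |r| below this at the optimum triggers a warning (EE looks unrelated to
#: activity; the fitted NEAT model is then meaningless).
LOW_CORRELATION_THRESHOLD = 0.2


class ZeroActivityVarianceError(ValueError):
    """Activity is constant over the requested period; no slope is defined."""


@dataclass(frozen=True)
class IntegrationSpec:
    """How activity is aggregated before relating it to EE.

    ``half_width`` w: the window spans [t+lag-w, t+lag+w] (2w+1 samples
    where the series permits); ``lag`` shifts the window relative to the EE
    sample it is paired with.
    """

    half_width: int
    lag: int = 0

    def __post_init__(self):
        if int(self.half_width) != self.half_width or self.half_width < 0:
            raise ValueError(f"half_width must be a non-negative integer, "
                             f"got {self.half_width!r}")
        if int(self.lag) != self.lag:
            raise ValueError(f"lag must be an integer, got {self.lag!r}")
        object.__setattr__(self, "half_width", int(self.half_width))
        object.__setattr__(self, "lag", int(self.lag))


def integrate_activity(activity, spec: IntegrationSpec, statistic: str = "mean"):
    """Windowed aggregate of activity at each minute.

    Windows are truncated at the series boundaries rather than padded or
    dropped; a sample whose window lies entirely outside the series is NaN
    (excluded downstream).  ``statistic`` is "mean" (default, keeps units
    counts/min) or "sum".
    """
    a = np.asarray(activity, dtype=float)
    if a.ndim != 1:
        raise ValueError("activity must be 1-D")
    n = a.size
    if spec.half_width == 0:
        # exact single-sample window: a pure lag shift
        out = np.full(n, np.nan)
        src_lo = max(spec.lag, 0)
        src_hi = min(n, n + spec.lag)
        if statistic not in ("mean", "sum"):
            raise ValueError(f"unknown statistic {statistic!r}")
        if src_hi > src_lo:
            out[src_lo - spec.lag:src_hi - spec.lag] = a[src_lo:src_hi]
        return out
    centre = np.arange(n) + spec.lag
    lo = np.clip(centre - spec.half_width, 0, n - 1)
    hi = np.clip(centre + spec.half_width, 0, n - 1)
    valid = (centre + spec.half_width >= 0) & (centre - spec.half_width <= n - 1)
    csum = np.concatenate(([0.0], np.cumsum(a)))
    total = csum[hi + 1] - csum[lo]
    if statistic == "mean":
        out = total / (hi - lo + 1)
    elif statistic == "sum":
        out = total
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out[~valid] = np.nan
    return out


def _pearson(x, y):
    """Pearson r of two equal-length vectors; NaN if either is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = np.sqrt(np.sum(xd * xd))
    sy = np.sqrt(np.sum(yd * yd))
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.sum(xd * yd) / (sx * sy))


def _as_slice(sel, n):
    if sel is None:
        return slice(0, n)
    if isinstance(sel, slice):
        return slice(*sel.indices(n))
    i0, i1 = sel
    return slice(int(i0), int(i1))


def optimize_integration(
    ee,
    activity,
    sel=None,
    half_widths=DEFAULT_HALF_WIDTHS,
    lags=DEFAULT_LAGS,
    statistic: str = "mean",
    min_samples: int = 10,
):
    """Exhaustive grid search for the (half-width, lag) maximizing Pearson r.

    The correlation is computed between ``ee[t]`` and the integrated
    activity at ``t`` for ``t`` in ``sel`` (a slice or (start, stop) index
    pair on the minute grid; the integration windows may reach outside
    ``sel``).  Ties break toward the smallest half-width, then the smallest
    |lag|, then non-positive lag.

    Returns ``(IntegrationSpec, r)`` at the optimum.
    """
    ee = np.asarray(ee, dtype=float)
    a = np.asarray(activity, dtype=float)
    if ee.shape != a.shape:
        raise ValueError("ee and activity must be aligned (equal length)")
    sl = _as_slice(sel, ee.size)
    if np.ptp(a[sl]) == 0.0:
        raise ZeroActivityVarianceError(
            "zero activity variance over the requested period"
        )
    ee_win = ee[sl]
    lag_order = sorted(lags, key=lambda lag: (abs(lag), lag > 0))
    best = None  # (r, spec)
    for w in sorted(set(int(w) for w in half_widths)):
        for lag in lag_order:
            spec = IntegrationSpec(w, int(lag))
            aint = integrate_activity(a, spec, statistic)[sl]
            ok = np.isfinite(aint)
            if int(ok.sum()) < min_samples:
                raise ZeroActivityVarianceError(
                    f"fewer than {min_samples} valid samples at "
                    f"(w={w}, lag={lag})"
                )
            r = _pearson(ee_win[ok], aint[ok])
            if np.isnan(r):
                continue
            if best is None or r > best[0]:
                best = (r, spec)
    if best is None:
        raise ZeroActivityVarianceError(
            "integrated activity constant at every grid point"
        )
    r, spec = best
    if abs(r) < LOW_CORRELATION_THRESHOLD:
        warnings.warn(
            f"max |r| = {abs(r):.3f} < {LOW_CORRELATION_THRESHOLD}: EE "
            "appears unrelated to activity over this period",
            stacklevel=2,
        )
    return spec, r


@dataclass(frozen=True)
class NeatFit:
    """Linear dependency of EE on integrated activity over one period.

    ``min_integrated_activity`` is the period minimum of the integrated
    series and serves as the zero-NEAT reference.  ``degenerate`` marks a
    non-positive slope (or a forced NEAT==0 fallback); the NEAT series is
    then identically zero.
    """

    spec: IntegrationSpec
    slope: float
    intercept: float
    r: float
    min_integrated_activity: float
    n_samples: int
    degenerate: bool = False
    statistic: str = "mean"
    period_name: str = ""

    @classmethod
    def null(cls, period_name: str = "", statistic: str = "mean"):
        """Fallback fit producing NEAT == 0 (constant-activity periods)."""
        return cls(
            spec=IntegrationSpec(0, 0),
            slope=0.0,
            intercept=float("nan"),
            r=0.0,
            min_integrated_activity=0.0,
            n_samples=0,
            degenerate=True,
            statistic=statistic,
            period_name=period_name,
        )


def fit_neat(
    ee,
    activity,
    sel=None,
    spec: IntegrationSpec = IntegrationSpec(0, 0),
    statistic: str = "mean",
    period_name: str = "",
) -> NeatFit:
    """OLS fit of ``ee`` on integrated activity over ``sel``."""
    ee = np.asarray(ee, dtype=float)
    a = np.asarray(activity, dtype=float)
    if ee.shape != a.shape:
        raise ValueError("ee and activity must be aligned (equal length)")
    sl = _as_slice(sel, ee.size)
    aint = integrate_activity(a, spec, statistic)[sl]
    y = ee[sl]
    ok = np.isfinite(aint)
    x, y = aint[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0.0:
        raise ZeroActivityVarianceError(
            "zero integrated-activity variance over the requested period"
        )
    xd = x - x.mean()
    slope = float(np.dot(xd, y - y.mean()) / np.dot(xd, xd))
    intercept = float(y.mean() - slope * x.mean())
    r = _pearson(x, y)
    if np.isnan(r):  # constant EE
        r = 0.0
    fit = NeatFit(
        spec=spec,
        slope=slope,
        intercept=intercept,
        r=r,
        min_integrated_activity=float(np.min(x)),
        n_samples=int(x.size),
        degenerate=slope <= 0.0,
        statistic=statistic,
        period_name=period_name,
    )
    if fit.degenerate:
        warnings.warn(
            f"non-positive EE~activity slope ({slope:.3g}) over "
            f"{period_name or 'period'}: NEAT set to 0",
            stacklevel=2,
        )
    return fit


def neat_series(fit: NeatFit, activity):
    """NEAT (kcal/min) at every minute: slope * excess integrated activity.

    Zero at (and below) the fitted period's minimum integrated activity.
    Boundary minutes whose integration window is empty get NEAT 0 (no
    information; they are outside every analysis period in practice).
    Degenerate fits yield an all-zero series.
    """
    a = np.asarray(activity, dtype=float)
    if fit.degenerate:
        return np.zeros_like(a)
    aint = integrate_activity(a, fit.spec, fit.statistic)
    excess = aint - fit.min_integrated_activity
    excess[~np.isfinite(excess)] = 0.0
    return fit.slope * np.clip(excess, 0.0, None)


def ee_free_series(ee, neat):
    """EE with the NEAT component removed: ``ee - neat`` elementwise."""
    ee = np.asarray(ee, dtype=float)
    neat = np.asarray(neat, dtype=float)
    if ee.shape != neat.shape:
        raise ValueError("ee and neat series are misaligned")
    return ee - neat
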