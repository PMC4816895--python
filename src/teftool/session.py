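"""Core data model for minute-resolution chamber sessions.

A :class:`CalorimetrySession` is a complete 1-min grid of energy expenditure
(kcal/min) and triaxial accelerometer activity (counts/min) over a single
chamber stay, together with the meal schedule.  All analysis windows are
expressed as wall-clock :class:`Period` objects and resolved against the
session's own minute grid, so a "4 h" period always contains exactly 240
samples.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Weir coefficients for EE (kcal/min) from VO2 (L/min), VCO2 (L/min) and
#: urinary nitrogen excretion rate (g/min).  Overridable per call / config.
WEIR_VO2_COEF = 3.941
WEIR_VCO2_COEF = 1.106
WEIR_NITROGEN_COEF = 2.17

MINUTE = pd.Timedelta(minutes=1)

_CLOCK_RE = re.compile(r"^([01]?\d|2[0-3]):([0-5]\d)$")


class SessionError(ValueError):
    """Session data violate the minute-grid contract."""


def parse_clock(text: str) -> int:
    """Parse ``"HH:MM"`` into minutes past midnight."""
    m = _CLOCK_RE.match(str(text).strip())
    if m is None:
        raise SessionError(f"not a valid HH:MM clock time: {text!r}")
    return int(m.group(1)) * 60 + int(m.group(2))


def format_clock(minute_of_day: int) -> str:
    return f"{minute_of_day // 60:02d}:{minute_of_day % 60:02d}"


@dataclass(frozen=True)
class MealEvent:
    """A meal at a wall-clock time with its energy content (kcal)."""

    time: str
    energy_kcal: float
    label: str = ""

    def __post_init__(self):
        parse_clock(self.time)  # validates format
        if not self.energy_kcal > 0:
            raise SessionError(
                f"meal energy must be > 0 kcal, got {self.energy_kcal!r}"
                + (f" ({self.label})" if self.label else "")
            )

    @property
    def minute_of_day(self) -> int:
        return parse_clock(self.time)


@dataclass(frozen=True)
class Period:
    """Half-open wall-clock window ``[start, end)`` on the minute grid.

    ``end`` may be clock-earlier than ``start``, in which case the window
    wraps midnight (e.g. the 23:00-07:00 sleep period spans 480 min).
    """

    start: str
    end: str
    name: str = ""

    def __post_init__(self):
        parse_clock(self.start)
        parse_clock(self.end)
        if self.duration_minutes == 0:
            raise SessionError(
                f"degenerate period {self.name or self.start}: start == end"
            )

    @property
    def duration_minutes(self) -> int:
        return (parse_clock(self.end) - parse_clock(self.start)) % 1440


@dataclass(frozen=True)
class GasRecord:
    """One minute of gas exchange: VO2/VCO2 (L/min), nitrogen rate (g/min)."""

    vo2: float
    vco2: float
    n_rate: float = 0.0

    def __post_init__(self):
        if self.vo2 < 0 or self.vco2 < 0 or self.n_rate < 0:
            raise SessionError("gas record values must be non-negative")
        if self.vo2 > 0:
            rq = self.vco2 / self.vo2
            if not (0.6 < rq < 1.3):
                warnings.warn(
                    f"respiratory quotient {rq:.3f} outside (0.6, 1.3)",
                    stacklevel=2,
                )


def weir_ee(vo2, vco2=None, n_rate=0.0, *, coefficients=None):
    """Energy expenditure (kcal/min) from gas exchange, Weir formulation.

    ``EE = 3.941*vo2 + 1.106*vco2 - 2.17*n_rate``.  Accepts a
    :class:`GasRecord` as sole argument, or scalar/array vo2+vco2(+n_rate).
    A negative result signals inconsistent inputs and raises.
    """
    if isinstance(vo2, GasRecord):
        g = vo2
        vo2, vco2, n_rate = g.vo2, g.vco2, g.n_rate
    if vco2 is None:
        raise TypeError("vco2 required unless a GasRecord is given")
    c_o2, c_co2, c_n = coefficients or (
        WEIR_VO2_COEF,
        WEIR_VCO2_COEF,
        WEIR_NITROGEN_COEF,
    )
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    n_rate = np.asarray(n_rate, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0) or np.any(n_rate < 0):
        raise SessionError("gas exchange inputs must be non-negative")
    ee = c_o2 * vo2 + c_co2 * vco2 - c_n * n_rate
    if np.any(ee < 0):
        raise SessionError("negative energy expenditure from gas exchange")
    if ee.ndim == 0:
        return float(ee)
    return ee


@dataclass
class CalorimetrySession:
    """Aligned minute series of EE and activity over one chamber stay."""

    timestamps: pd.DatetimeIndex
    ee: np.ndarray
    activity: np.ndarray
    meals: tuple = ()
    condition: str = ""

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.ee = np.asarray(self.ee, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.meals = tuple(self.meals)
        n = len(self.timestamps)
        if not (len(self.ee) == len(self.activity) == n):
            raise SessionError(
                f"length mismatch: {n} timestamps, {len(self.ee)} ee, "
                f"{len(self.activity)} activity"
            )
        if n < 2:
            raise SessionError("session needs at least 2 samples")
        diffs = np.diff(self.timestamps.asi8)
        bad = np.nonzero(diffs != 60_000_000_000)[0]
        if bad.size:
            i = int(bad[0])
            d = pd.Timedelta(diffs[i], unit="ns")
            if diffs[i] <= 0:
                raise SessionError(
                    f"duplicate/non-increasing timestamp at "
                    f"{self.timestamps[i + 1]}"
                )
            if d % MINUTE == pd.Timedelta(0):
                missing = self.timestamps[i] + MINUTE
                raise SessionError(f"gap at {missing}")
            raise SessionError(
                f"non-1-min spacing ({d}) after {self.timestamps[i]}"
            )
        if np.any(~np.isfinite(self.ee)) or np.any(self.ee < 0):
            raise SessionError("ee must be finite and >= 0 everywhere")
        if np.any(~np.isfinite(self.activity)) or np.any(self.activity < 0):
            raise SessionError("activity must be finite and >= 0 everywhere")
        for meal in self.meals:
            self.locate(meal.time)  # raises if outside span

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def minutes_of_day(self) -> np.ndarray:
        t = self.timestamps
        return (t.hour * 60 + t.minute).to_numpy()

    def locate(self, clock: str) -> int:
        """Index of the first sample whose wall clock equals ``clock``."""
        target = parse_clock(clock)
        hits = np.nonzero(self.minutes_of_day == target)[0]
        if hits.size == 0:
            raise SessionError(f"clock time {clock} not in session span")
        return int(hits[0])

    def period_slice(self, period: Period) -> slice:
        """Resolve a wall-clock period to an index slice on the grid."""
        i0 = self.locate(period.start)
        i1 = i0 + period.duration_minutes
        if i1 > len(self):
            raise SessionError(
                f"period {period.name or period.start} extends past session end"
            )
        return slice(i0, i1)

    def slice(self, period: Period):
        """EE and activity subseries for ``period`` (half-open)."""
        sel = self.period_slice(period)
        return self.ee[sel].copy(), self.activity[sel].copy()

    def meal_index(self, meal: MealEvent) -> int:
        return self.locate(meal.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "ee_kcal_min": self.ee,
                "activity_counts": self.activity,
            }
        )


def advance_ee(session: CalorimetrySession, minutes: int) -> CalorimetrySession:
    """Shift EE earlier by ``minutes`` to undo calorimeter response delay.

    The trailing ``minutes`` samples lose their EE value, so all series are
    truncated to the common support; nothing is padded or fabricated.
    """
    minutes = int(minutes)
    if minutes < 0:
        raise SessionError("advance must be >= 0 minutes")
    if minutes >= len(session):
        raise SessionError(
            f"advance of {minutes} min >= session length {len(session)}"
        )
    if minutes == 0:
        return replace(session)
    n = len(session) - minutes
    meals = tuple(
        m
        for m in session.meals
        if any(
            (session.timestamps[:n].hour * 60 + session.timestamps[:n].minute)
            == m.minute_of_day
        )
    )
    return CalorimetrySession(
        timestamps=session.timestamps[:n],
        ee=session.ee[minutes:].copy(),
        activity=session.activity[:n].copy(),
        meals=meals,
        condition=session.condition,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_CANONICAL_COLUMNS = {
    "timestamp": "timestamp",
    "ee": "ee_kcal_min",
    "activity": "activity_counts",
    "vo2": "vo2_l_min",
    "vco2": "vco2_l_min",
}


def _fill_gaps(frame: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    full = pd.date_range(frame.index[0], frame.index[-1], freq="1min")
    missing = full.difference(frame.index)
    if missing.empty:
        return frame
    out = frame.reindex(full)
    runs = (missing.to_series().diff() != MINUTE).cumsum()
    longest = int(runs.value_counts().max())
    if longest > max_gap:
        raise SessionError(
            f"gap of {longest} min exceeds --max-gap {max_gap}"
        )
    logger.info("filling %d missing minute(s) by linear interpolation",
                len(missing))
    return out.interpolate(method="time", limit_direction="both")


def read_session(
    path,
    schema: dict | None = None,
    *,
    n_rate: float = 0.0,
    meals=(),
    condition: str = "",
    fill_gaps: bool = False,
    max_gap: int = 5,
    weir_coefficients=None,
) -> CalorimetrySession:
    """Load a session from delimited text.

    The table must carry a timestamp column plus either an EE column or
    VO2+VCO2 columns (EE then computed via :func:`weir_ee` with the
    session-level constant ``n_rate``), and an activity column.  ``schema``
    maps the canonical names (``timestamp``, ``ee``, ``activity``, ``vo2``,
    ``vco2``) to the file's actual column names.
    """
    names = dict(_CANONICAL_COLUMNS)
    names.update(schema or {})
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if names["timestamp"] not in df.columns:
        raise SessionError(f"missing column {names['timestamp']!r}")
    ts = pd.to_datetime(df[names["timestamp"]])
    dup = ts[ts.duplicated()]
    if not dup.empty:
        raise SessionError(f"duplicate timestamp at {dup.iloc[0]}")
    df = df.set_index(pd.DatetimeIndex(ts))

    if names["ee"] in df.columns:
        keep = [names["ee"], names["activity"]]
    elif names["vo2"] in df.columns and names["vco2"] in df.columns:
        keep = [names["vo2"], names["vco2"], names["activity"]]
    else:
        raise SessionError(
            "need either an EE column or VO2+VCO2 columns"
        )
    if names["activity"] not in df.columns:
        raise SessionError(f"missing column {names['activity']!r}")
    df = df[keep].astype(float)

    if fill_gaps:
        df = _fill_gaps(df, max_gap)
    else:
        diffs = np.diff(df.index.asi8)
        gaps = np.nonzero(diffs > 60_000_000_000)[0]
        if gaps.size and diffs[gaps[0]] % 60_000_000_000 == 0:
            raise SessionError(f"gap at {df.index[gaps[0]] + MINUTE}")
        # other spacing problems fall through to session validation

    if names["ee"] in df.columns:
        ee = df[names["ee"]].to_numpy()
    else:
        ee = weir_ee(
            df[names["vo2"]].to_numpy(),
            df[names["vco2"]].to_numpy(),
            n_rate,
            coefficients=weir_coefficients,
        )
    return CalorimetrySession(
        timestamps=df.index,
        ee=ee,
        activity=df[names["activity"]].to_numpy(),
        meals=tuple(meals),
        condition=condition,
    )


def write_session(session: CalorimetrySession, path, header_comments=()):
    """Write a session as the canonical CSV (values round-trip bit-exact)."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame = session.to_frame()
        frame["timestamp"] = frame["timestamp"].dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_meals(path) -> tuple:
    """Read a meals CSV with header ``time,energy_kcal,label``.

    ``time`` may be "HH:MM" or a full timestamp (only the clock is kept).
    """
    df = pd.read_csv(path, comment="#", dtype={"time": str})
    for col in ("time", "energy_kcal"):
        if col not in df.columns:
            raise SessionError(f"meals file missing column {col!r}")
    meals = []
    for _, row in df.iterrows():
        t = str(row["time"]).strip()
        if not _CLOCK_RE.match(t):
            ts = pd.Timestamp(t)
            t = f"{ts.hour:02d}:{ts.minute:02d}"
        meals.append(
            MealEvent(
                time=t,
                energy_kcal=float(row["energy_kcal"]),
                label=str(row.get("label", "") or ""),
            )
        )
    return tuple(meals)


def write_meals(meals, path, header_comments=()):
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("time,energy_kcal,label\n")
        for m in meals:
            fh.write(f"{m.time},{m.energy_kcal:.17g},{m.label}\n")
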