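import dataclasses

import numpy as np
import pandas as pd
import pytest

from teftool import CalorimetrySession, MealEvent, SimulationParams
from teftool.simulate import DEFAULT_MEALS


def make_session(ee, activity, start="2000-01-01 07:00", meals=(), condition=""):
    ee = np.asarray(ee, dtype=float)
    ts = pd.date_range(start, periods=len(ee), freq="1min")
    return CalorimetrySession(
        timestamps=ts,
        ee=ee,
        activity=np.asarray(activity, dtype=float),
        meals=tuple(meals),
        condition=condition,
    )


@pytest.fixture
def session_factory():
    return make_session


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


def flat_response_meals(tef_fraction=None):
    """Meals with a boxcar-like 4-h response fully inside the window."""
    meals = []
    for m in DEFAULT_MEALS:
        kwargs = dict(response_shape=1.0, response_scale=1e7,
                      response_support_min=240)
        if tef_fraction is not None:
            kwargs["tef_fraction"] = tef_fraction
        meals.append(dataclasses.replace(m, **kwargs))
    return tuple(meals)


def exact_recovery_params(**overrides):
    """Zero-noise regime where the NEAT-free method's assumptions hold
    exactly: no EE noise, no activity jitter, flat circadian basal, sparse
    strong bursts, and the true integration kernel on the search grid."""
    kwargs = dict(
        noise_sd=0.0,
        activity_jitter_sd=0.0,
        sleep_jitter_sd=0.0,
        circadian_amplitude=0.0,
        burst_rate=2.0,
        burst_magnitude=4000.0,
        burst_duration_range=(2, 5),
        neat_slope=3e-4,
        neat_kernel_half_width=4,
        neat_kernel_lag=0,
        meals=flat_response_meals(),
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


@pytest.fixture(scope="session")
def exact_params():
    return exact_recovery_params()


@pytest.fixture(scope="session")
def meal_event_breakfast():
    return MealEvent("08:00", 689.0, "breakfast")
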