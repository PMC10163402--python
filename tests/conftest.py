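import datetime as dt

import numpy as np
import pytest

from stepdyn.arx import ArxCoefficients
from stepdyn.synthetic_cohort import ParticipantSpec, SimulationConfig


def first_order(a1: float, b0, a0: float = 0.0) -> ArxCoefficients:
    """Ground-truth coefficients with one output lag and lag-0 inputs only."""
    a = np.zeros(5)
    a[0] = a1
    b = np.zeros((3, 6))
    b[:, 0] = np.asarray(b0, dtype=float)
    return ArxCoefficients(a0=a0, a=a, b=b)


@pytest.fixture
def simple_spec() -> ParticipantSpec:
    return ParticipantSpec(
        participant_id="p000",
        weekday_coeffs=first_order(0.4, [120.0, 60.0, -30.0], a0=90.0),
        weekend_coeffs=first_order(0.6, [200.0, 100.0, -50.0], a0=60.0),
        window_start=480,  # 08:00
        window_end=1200,  # 20:00
        baseline_rate=6.0,
        noise_sd=0.0,
        hr_dropout_prob=0.0,
        nonwear_blocks_per_week=0.0,
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_participants=1, n_days=7, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_minutes(day: dt.date, start: int, steps, hr=None):
    """Minute-table DataFrame from a step list starting at minute-of-day."""
    import pandas as pd

    steps = list(steps)
    if hr is None:
        hr = [1] * len(steps)
    base = dt.datetime.combine(day, dt.time(0, 0))
    return pd.DataFrame(
        {
            "timestamp": [base + dt.timedelta(minutes=start + i) for i in range(len(steps))],
            "steps": steps,
            "hr_present": list(hr),
        }
    )
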