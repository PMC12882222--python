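import numpy as np
import pandas as pd
import pytest


def standardize(v):
    v = np.asarray(v, dtype=float)
    return (v - v.mean()) / v.std()


def sinusoid_day(n=1440, lag_minutes=0, phase_hours=13.0):
    """Standardized cosine day; returns (light, activity lagging by lag_minutes)."""
    t = np.arange(n)
    light = np.cos((t / n * 24.0 - phase_hours) * 2 * np.pi / 24.0)
    activity = np.roll(light, lag_minutes)
    return standardize(light), standardize(activity)


def xcorr_bruteforce(x, y):
    """O(N^2) reference implementation of the circular cross-correlation."""
    n = len(x)
    return np.array([np.dot(x, np.roll(y, -tau)) / n for tau in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    from phasorckm import CohortSimSpec, simulate_cohort

    return simulate_cohort(CohortSimSpec(n=1200, seed=99))
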