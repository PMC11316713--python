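import numpy as np
import pandas as pd
import pytest

from ultradian import synth

ZERO_NOISE = {"mr": 0.0, "rer": 0.0, "tb": 0.0, "activity": 0.0}


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free default conditions."""
    return synth.SynthConfig(seed=7, noise_sd=ZERO_NOISE)


@pytest.fixture(scope="session")
def default_day(default_config):
    return synth.generate_day(default_config, 0)


@pytest.fixture(scope="session")
def quiet_day(quiet_config):
    return synth.generate_day(quiet_config, 0)


def make_day(mr=None, rer=None, tb=None, activity=None, light_phase=(8.0, 16.0)):
    """Hand-built PhysioDay for constructed examples."""
    n = synth.N_MINUTES
    ts = pd.date_range("2023-01-01", periods=n, freq="min")
    return synth.PhysioDay(
        timestamps=ts,
        mr=None if mr is None else np.asarray(mr, dtype=float),
        rer=None if rer is None else np.asarray(rer, dtype=float),
        tb=None if tb is None else np.asarray(tb, dtype=float),
        activity=None if activity is None else np.asarray(activity, dtype=float),
        light_phase=light_phase,
    )


def triangle_burst(n, t_min, t_peak, base, peak, decay=None):
    """Piecewise-linear burst rising from (t_min, base) to (t_peak, peak)."""
    x = np.full(n, base, dtype=float)
    rise = t_peak - t_min
    for k in range(rise + 1):
        x[t_min + k] = base + (peak - base) * k / rise
    d = decay if decay is not None else rise
    for k in range(1, d + 1):
        if t_peak + k < n:
            x[t_peak + k] = peak - (peak - base) * k / d
    return x
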