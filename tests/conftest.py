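import numpy as np
import pandas as pd
import pytest

from darkcut import climate, simulate


@pytest.fixture(scope="session")
def week_series():
    """One full week of synthetic 15-min indices for a single station."""
    conf = simulate.WeatherSimConfig(
        start_date="2018-01-01", n_days=9, seed=12
    )
    obs = simulate.simulate_weather(conf)
    return climate.index_series(obs, climate.HliParams())


@pytest.fixture(scope="session")
def small_herd():
    """A ~3,000-animal herd with outcomes, no climate attached."""
    conf = simulate.HerdSimConfig(seed=5).scaled(3000)
    return simulate.simulate_outcomes(simulate.simulate_herd(conf), conf), conf


def make_flat_series(hli_values, start="2018-01-01", interval_min=15,
                     ta=20.0, rh=50.0, sr=0.0, ws=1.0, rain=0.0):
    """Index-series frame with prescribed HLI values (other fields flat)."""
    n = len(hli_values)
    ts = pd.date_range(start, periods=n, freq=f"{interval_min}min")
    return pd.DataFrame({
        "timestamp": ts,
        "ta": ta, "rh": rh, "sr": sr, "ws": ws, "rain": rain,
        "bgt": ta, "thi": 60.0,
        "hli": np.asarray(hli_values, dtype=float),
        "ahl": 0.0,
    })
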