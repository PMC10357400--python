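import numpy as np
import pandas as pd
import pytest

from scorrflow import LaserGeometry, SimulationConfig


@pytest.fixture
def geom():
    return LaserGeometry(dx1=1.0, dx2=1.0, dx3=15.0)


@pytest.fixture
def small_config():
    return SimulationConfig(arrival_rate=35.0, duration=10.0, seed=7)


def make_peaks(times_ms, pts_ms, heights=None, channel="red", ids=None, brightness=None):
    """Hand-build a peak table in the package schema."""
    times = np.asarray(times_ms, dtype=float)
    n = times.size
    df = pd.DataFrame(
        {
            "channel": channel,
            "t_center_ms": times,
            "height": np.ones(n) if heights is None else np.asarray(heights, float),
            "pt_ms": np.asarray(pts_ms, dtype=float),
            "fit_quality": 1.0,
        }
    )
    if ids is not None:
        df["true_particle_id"] = np.asarray(ids)
    if brightness is not None:
        df["brightness_class"] = np.asarray(brightness)
    return df
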