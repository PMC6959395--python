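import numpy as np
import pandas as pd
import pytest

from mobisym.pipeline import featurize
from mobisym.simulate import SimulationConfig, simulate_cohort

DEG_PER_KM = 1.0 / 111.19492664455873  # 360 / (2 pi 6371) — exact on a meridian


def points_frame(rows, user="u0"):
    """Build a location-point table from (timestamp, lat, lon, accuracy) rows."""
    return pd.DataFrame(
        {
            "user_id": user,
            "latitude": [r[1] for r in rows],
            "longitude": [r[2] for r in rows],
            "source": "GPS",
            "accuracy_m": [r[3] if len(r) > 3 else 10.0 for r in rows],
            "timestamp": pd.to_datetime([r[0] for r in rows], utc=True),
        }
    )


def stops_frame(rows, user="u0"):
    """Build a stop table from (place_id, t_arrival, t_departure, lat, lon) rows."""
    return pd.DataFrame(
        {
            "user_id": user,
            "place_id": [r[0] for r in rows],
            "t_arrival": pd.to_datetime([r[1] for r in rows], utc=True),
            "t_departure": pd.to_datetime([r[2] for r in rows], utc=True),
            "centroid_lat": [r[3] for r in rows],
            "centroid_lon": [r[4] for r in rows],
            "label": "other",
        }
    )


@pytest.fixture(scope="session")
def small_signal_cohort():
    """A compact cohort with a strong mobility-contraction effect, shared by
    the recovery-style tests."""
    config = SimulationConfig(n_users=10, n_days=30, seed=11, effect_size=0.6)
    locations, symptoms, episodes = simulate_cohort(config)
    return config, locations, symptoms, episodes


@pytest.fixture(scope="session")
def small_signal_daily(small_signal_cohort):
    _, locations, _, _ = small_signal_cohort
    return featurize(locations)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
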