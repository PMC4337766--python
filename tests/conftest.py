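import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dielmove.trajectory import GpsTrack

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_track(lat, lon, success=None, individual_id="A", start="2001-01-01 00:00"):
    lat = np.asarray(lat, dtype=float)
    times = pd.date_range(start, periods=len(lat), freq="h")
    if success is None:
        success = np.ones(len(lat), dtype=bool)
    return GpsTrack(individual_id, times, lat, np.asarray(lon, dtype=float), np.asarray(success))


@pytest.fixture(scope="session")
def equator_walk_track():
    """25 hourly fixes stepping 0.01 degrees of longitude along the equator."""
    n = 25
    return make_track(np.zeros(n), 37.0 + 0.01 * np.arange(n))


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared by pipeline-level tests."""
    from dielmove.synthetic import SimulationConfig, simulate_dataset

    config = SimulationConfig(seed=402, n_days=400)
    tracks, ndvi, ranks, truth = simulate_dataset(config)
    return {"config": config, "tracks": tracks, "ndvi": ndvi, "ranks": ranks, "truth": truth}
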