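import datetime as dt

import numpy as np
import pytest

from pseudotrack import (
    BiasedWalkConfig,
    GeoPosition,
    SyntheticEnvConfig,
    TimedFix,
    Track,
    TrackSet,
    backward_rolling_mean,
    generate_env,
)


@pytest.fixture(scope="session")
def gradient_field():
    """Deterministic field warming strictly northward, no noise/gaps."""
    cfg = SyntheticEnvConfig(
        lat_min=20.0, lat_max=35.0, lon_min=-140.0, lon_max=-125.0,
        cell_size_deg=1.0 / 12.0, n_days=40, base_sst=15.0,
        meridional_gradient=+0.5, eddy_amplitude=0.0, seasonal_amplitude=0.0,
        noise_sd=0.0, missing_fraction=0.0, seed=0,
    )
    return generate_env(cfg)


@pytest.fixture(scope="session")
def realistic_field():
    """Smaller-domain field with the full default statistical structure."""
    cfg = SyntheticEnvConfig(
        lat_min=25.0, lat_max=40.0, lon_min=-145.0, lon_max=-122.0,
        n_days=40, seed=11,
    )
    return generate_env(cfg)


@pytest.fixture(scope="session")
def realistic_rolled(realistic_field):
    return backward_rolling_mean(realistic_field, 8)


def make_track(track_id, start_date, positions, ci=None):
    fixes = [
        TimedFix(start_date + dt.timedelta(days=i), GeoPosition(la, lo), ci)
        for i, (la, lo) in enumerate(positions)
    ]
    return Track(track_id, fixes)


@pytest.fixture
def simple_track():
    return make_track("t1", dt.date(2004, 1, 15),
                      [(30.0, -135.0), (30.0, -134.5), (30.5, -134.5), (30.5, -134.0)])
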