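import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import leafwue as lw
from leafwue.params import ModelParams
from leafwue.simulator import SimConfig, run

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def sunny_day() -> lw.ClimateSeries:
    return lw.make_ideal_day(lw.SUNNY)


@pytest.fixture(scope="session")
def cloudy_day() -> lw.ClimateSeries:
    return lw.make_ideal_day(lw.CLOUDY)


@pytest.fixture(scope="session")
def sunny_trace_dt5(sunny_day):
    return run(SimConfig(dt=5.0), sunny_day)


@pytest.fixture
def tiny_series() -> lw.ClimateSeries:
    """Three-sample constant-CO2 series for interpolation tests."""
    return lw.ClimateSeries(
        t=np.array([0.0, 600.0, 1200.0]),
        ppfd=np.array([100.0, 200.0, 150.0]),
        ta=np.array([293.15, 295.15, 294.15]),
        hr=np.array([80.0, 70.0, 75.0]),
        ca=np.array([380.0, 380.0, 380.0]),
    )
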