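import numpy as np
import pytest

from carbonledger import FluxSeries, WorldConfig, simulate_world


@pytest.fixture(scope="session")
def world():
    """One deterministic synthetic world shared across read-only tests."""
    return simulate_world(WorldConfig(seed=7))


@pytest.fixture()
def years():
    return np.arange(1960, 2024)


def make_series(values, component="X", first_year=2000, sigma=None):
    values = np.asarray(values, float)
    yrs = np.arange(first_year, first_year + values.size)
    return FluxSeries(component, yrs, values, sigma)


@pytest.fixture()
def series_factory():
    return make_series
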