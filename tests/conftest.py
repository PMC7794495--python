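import numpy as np
import pandas as pd
import pytest

from owlfam import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SimulationConfig(seed=42, n_nests_urban=60, n_nests_rural=60,
                               n_years=8)


@pytest.fixture(scope="session")
def nests(small_config):
    return sd.simulate_landscape(small_config)


@pytest.fixture(scope="session")
def events(small_config, nests):
    return sd.simulate_breeding_seasons(nests, small_config)


@pytest.fixture(scope="session")
def chicks(small_config, events):
    return sd.simulate_chicks(events, small_config)


@pytest.fixture(scope="session")
def triangle_nests():
    """Three nests pairwise 1 km apart (equilateral triangle)."""
    return pd.DataFrame({
        "nest_id": ["a", "b", "c"],
        "habitat": ["urban"] * 3,
        "x_km": [0.0, 1.0, 0.5],
        "y_km": [0.0, 0.0, np.sqrt(3) / 2],
    })
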