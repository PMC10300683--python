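import numpy as np
import pandas as pd
import pytest

from isoniche import default_config, simulate_population


@pytest.fixture(scope="session")
def sim_data():
    """One default synthetic dataset shared across tests (fixed seed)."""
    return simulate_population(default_config(), seed=20230628)


@pytest.fixture(scope="session")
def scute(sim_data):
    return sim_data[1]


@pytest.fixture(scope="session")
def epidermis(sim_data):
    return sim_data[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def balanced_scute(rng, n_turtles=6, n_layers=4, sigma_b=1.5, sigma_w=0.8, layer_slope=0.0):
    """Small balanced repeated-measures table with known components."""
    b = rng.normal(0.0, sigma_b, n_turtles)
    rows = []
    for i in range(n_turtles):
        for j in range(1, n_layers + 1):
            rows.append({
                "turtle_id": f"T{i}",
                "tissue": "scute",
                "layer": j,
                "d13C": -16.0 + b[i] + layer_slope * (j - 1) + rng.normal(0, sigma_w),
                "d15N": 6.0 + b[i] + rng.normal(0, sigma_w),
                "cclmin": 70.0 + i,
                "lifestage": "subadult",
                "sex": "unknown",
            })
    return pd.DataFrame(rows)
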