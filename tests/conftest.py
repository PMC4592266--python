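import numpy as np
import pandas as pd
import pytest

from densnest.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated dataset shared across read-only tests."""
    return simulate_dataset(SimConfig(seed=11, n_farms=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(202)


def random_points(rng, n, scale=500.0, farm="F1", year=2007):
    pts = pd.DataFrame(
        {
            "territory_id": [f"T{i}" for i in range(n)],
            "farm_id": farm,
            "year": year,
            "x": rng.uniform(0, scale, n),
            "y": rng.uniform(0, scale, n),
        }
    )
    return pts
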