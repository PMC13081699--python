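import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from brainage import SimulationConfig, generate_parcellation, simulate_cohort

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def parcellation400():
    return generate_parcellation(400, 7, seed=0)


@pytest.fixture(scope="session")
def small_parcellation():
    return generate_parcellation(14, 7, seed=0)


@pytest.fixture(scope="session")
def full_cohort():
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_parcellation():
    """4 ROIs, 2 networks, 2 hemispheres — small enough to hand-count."""
    return pd.DataFrame({
        "roi": [0, 1, 2, 3],
        "name": ["L_A_1", "L_B_1", "R_A_1", "R_B_1"],
        "network": ["A", "B", "A", "B"],
        "hemisphere": ["L", "L", "R", "R"],
        "x": [-30.0, -40.0, 30.0, 40.0],
        "y": [0.0, 10.0, 0.0, 10.0],
        "z": [20.0, 30.0, 20.0, 30.0],
    })
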