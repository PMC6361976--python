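import numpy as np
import pandas as pd
import pytest

from splsnet.synthetic import make_marker_map, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small simulated dataset: 10 genes, 200 segregants."""
    return simulate_dataset(n=200, p=10, seed=42, noise_sd=0.3, acyclic=True)


@pytest.fixture(scope="session")
def marker_map():
    return make_marker_map(n_chromosomes=2, markers_per_chromosome=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_marker_map(distance_cm: float, same_chromosome: bool = True) -> pd.DataFrame:
    chroms = ["chr01", "chr01"] if same_chromosome else ["chr01", "chr02"]
    return pd.DataFrame(
        {
            "marker_id": ["mA", "mB"],
            "chromosome": chroms,
            "genetic_position": [0.0, distance_cm if same_chromosome else 0.0],
            "physical_position": [1000, 2000],
        }
    )
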