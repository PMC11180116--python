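import warnings

import numpy as np
import pandas as pd
import pytest

from nectarevo.phylo import read_newick_string
from nectarevo.synthetic_data import SimulationConfig, simulate_dataset

warnings.filterwarnings("ignore", message=".*tree is not ultrametric.*")


@pytest.fixture
def three_tip_tree():
    """((A:10,B:10):5,C:15); ultrametric, height 15."""
    return read_newick_string("((A:10,B:10):5,C:15);")


@pytest.fixture
def star_tree():
    return read_newick_string("(A:7,B:7,C:7);")


@pytest.fixture(scope="session")
def small_dataset():
    """One deterministic synthetic study at reduced size, shared by tests."""
    cfg = SimulationConfig(seed=42, n_species=60, n_pollinators=30,
                           n_network_plants=40, n_sites=4, visits_per_network=80)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_proportion_data(seed, n=200, beta=1.0, intercept=0.3, noise=0.1):
    """Fractional-proportion regression data with a single predictor."""
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    mu = 1.0 / (1.0 + np.exp(-(intercept + beta * x)))
    y = np.clip(mu + r.normal(0, noise, n), 0.0, 1.0)
    return pd.DataFrame({"y": y, "x": x})
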