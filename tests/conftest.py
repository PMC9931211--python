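import numpy as np
import pandas as pd
import pytest

from handclasp import Dataset, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A small but non-trivial study: 2 groups x 8, 300 events."""
    return SimulationConfig(group_sizes=(8, 8), n_events=300, sigma_I=0.5,
                            p_mother_known=0.5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ds, truth = simulate_dataset(small_config, seed=42)
    return ds, truth


@pytest.fixture()
def tiny_tables():
    """Hand-written four-table dataset: 2 groups x 2 individuals, 1 window."""
    individuals = pd.DataFrame({
        "id": ["A", "B", "C", "D"],
        "group": [1, 1, 2, 2],
        "sex": [1, 0, 0, 1],
        "mother_id": [None, None, None, None],
        "birth_year": [2000.0, 2010.0, 1995.0, 2012.0],
    })
    windows = pd.DataFrame({"window_id": ["w1"], "year": [2019.0]})
    ranks = pd.DataFrame({
        "window_id": ["w1"] * 12,
        "individual_id": ["A", "B", "C", "D"] * 3,
        "rater_id": np.repeat(["r1", "r2", "r3"], 4),
        "ordinal_rank": [1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 2, 1],
    })
    events = pd.DataFrame({
        "event_id": ["e1", "e2", "e3"],
        "window_id": ["w1"] * 3,
        "g1_id": ["A", "A", "C"],
        "g2_id": ["B", "B", "D"],
        "y_g1": [5, 1, 5],
        "y_g2": [5, 2, 5],
    })
    return individuals, windows, ranks, events


@pytest.fixture()
def tiny_dataset(tiny_tables):
    return Dataset(*tiny_tables)
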