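import numpy as np
import pandas as pd
import pytest

import longirt as L


@pytest.fixture(scope="session")
def logistic():
    return L.CdfSpec("logistic")


@pytest.fixture(scope="session")
def all_cdfs():
    return [L.CdfSpec(n) for n in ("logistic", "gaussian", "gumbel_min", "gumbel_max")]


@pytest.fixture(scope="session")
def item9():
    """The pain item with the published threshold estimates."""
    return L.Item("item9", 4, (-2.1, 1.0, 2.75))


@pytest.fixture(scope="session")
def cumulative_logistic():
    return L.ModelSpec("cumulative", "logistic")


@pytest.fixture(scope="session")
def tiny_dataset():
    """2 subjects x 2 visits x 1 item, for brute-force likelihood checks."""
    bank = L.ItemBank((L.Item("i1", 4, (-1.6, 1.0, 1.45)),))
    df = pd.DataFrame(
        {
            "subject_id": [1, 1, 2, 2],
            "group": 0,
            "time": [0.0, 4.0, 0.0, 4.0],
            "item_id": "i1",
            "response": [0, 2, 3, 1],
        }
    )
    return L.ResponseDataset(df, bank)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset reused by several estimation tests."""
    preset = L.ScenarioPreset(
        ratio="adjacent",
        beta1=0.3,
        sigma1_sq=0.2,
        n_subjects=80,
        visit_times=(0.0, 1.0, 2.0, 4.0),
        seed=2024,
    )
    return L.simulate_dataset(preset)


def random_etas(rng, M, scale=3.0):
    """Descending-order predictors valid for every family (decreasing etas
    satisfy the cumulative ordering requirement)."""
    etas = np.sort(rng.normal(0.0, scale, size=M))[::-1]
    etas[:-1] += 1e-3  # strictness
    return etas
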