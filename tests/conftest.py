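import numpy as np
import pandas as pd
import pytest

from dietmetrics import SimConfig, generate_study
from dietmetrics.metric_scoring import GDQSScoreTable


@pytest.fixture(scope="session")
def toy_gdqs_table() -> GDQSScoreTable:
    return GDQSScoreTable.toy()


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared across tests (seeded, deterministic)."""
    return generate_study(SimConfig(seed=42, n_participants=150))


@pytest.fixture()
def tiny_foods() -> pd.DataFrame:
    """Three-food catalog over two groups with simple nutrient values."""
    return pd.DataFrame({
        "food_id": ["f1", "f2", "f3"],
        "name": ["food 1", "food 2", "food 3"],
        "group_id": ["A", "A", "B"],
        "iron": [10.0, 5.0, 7.0],
        "energy_kcal": [100.0, 200.0, 50.0],
    }).set_index("food_id")
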