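import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bentho import CommunityTable, EnvTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def tiny_table():
    """2 samples x 2 taxa with known counts."""
    counts = pd.DataFrame(
        [[5, 0], [1, 3]], index=["S1", "S2"], columns=["T1", "T2"]
    )
    return CommunityTable(counts=counts)


@pytest.fixture
def seasonal_table():
    """12 samples across 4 seasons with structured counts."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.integers(0, 60, size=(12, 30)),
        index=[f"S{i:02d}" for i in range(12)],
        columns=[f"T{j:02d}" for j in range(30)],
    )
    seasons = np.repeat(["Spr", "Sum", "Aut", "Win"], 3)
    md = pd.DataFrame({"season": seasons}, index=counts.index)
    return CommunityTable(counts=counts, sample_metadata=md)


@pytest.fixture
def random_env(seasonal_table):
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(size=(seasonal_table.n_samples, 3)),
        index=seasonal_table.sample_ids,
        columns=["Temp", "DO", "pH"],
    )
    return EnvTable(values=values)
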