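import numpy as np
import pandas as pd
import pytest

from bromebiogeo import CountTable, SyntheticConfig, generate_neutral, generate_niche


@pytest.fixture
def toy_counts() -> CountTable:
    """3 ASVs x 4 samples, two groups, hand-written."""
    df = pd.DataFrame(
        {
            "s1": [6, 2, 0],
            "s2": [2, 2, 0],
            "s3": [0, 1, 9],
            "s4": [0, 0, 5],
        },
        index=pd.Index(["a", "b", "c"], name="asv_id"),
    )
    groups = pd.Series(
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, name="group"
    )
    return CountTable(df, groups)


def random_table(rng: np.random.Generator, n_asvs: int = 10, n_samples: int = 6,
                 max_count: int = 50) -> CountTable:
    mat = rng.integers(0, max_count, size=(n_asvs, n_samples))
    # ensure no all-zero samples
    mat[0, :] += 1
    df = pd.DataFrame(
        mat,
        index=pd.Index([f"asv{i}" for i in range(n_asvs)], name="asv_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    groups = pd.Series(
        {f"s{j}": ("A" if j < n_samples // 2 else "B") for j in range(n_samples)}
    )
    return CountTable(df, groups)


@pytest.fixture(scope="session")
def small_niche_dataset():
    """Niche-structured dataset at reduced scale (pool 800) for fast tests."""
    cfg = SyntheticConfig(pool_size=800, depth_range=(2000, 4000), seed=11)
    return generate_niche(cfg)


@pytest.fixture(scope="session")
def small_neutral_dataset():
    cfg = SyntheticConfig(pool_size=800, depth_range=(2000, 4000), seed=12)
    return generate_neutral(cfg)
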