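import numpy as np
import pandas as pd
import pytest

from metabopress.simulate import SimConfig, simulate_cohorts


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Six strata x 10 samples per cohort, 30 features in 10 blocks."""
    return SimConfig(
        n_discovery=(10,) * 6,
        n_validation=(10,) * 6,
        n_features=30,
        n_clusters=10,
        n_causal=2,
        effect_sizes=0.8,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohorts(tiny_config):
    return simulate_cohorts(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def two_block_features(rng) -> pd.DataFrame:
    """Six features: two well-separated 3-blocks (within |r| ~ 0.95, across ~ 0)."""
    n = 400
    blocks = []
    for _ in range(2):
        latent = rng.standard_normal(n)
        blocks.append(
            np.column_stack(
                [latent + 0.2 * rng.standard_normal(n) for _ in range(3)]
            )
        )
    data = np.hstack(blocks)
    return pd.DataFrame(data, columns=[f"f{k}" for k in range(6)])
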