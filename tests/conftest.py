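import numpy as np
import pytest

from voxconn.datasets import SourceTargetDataset
from voxconn.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Default small-scale synthetic atlas used across modules."""
    return SyntheticConfig(
        n_regions=6,
        grid_dims_expr=(8, 6, 7),
        n_genes=12,
        latent_dim=3,
        effect_size=4.0,
        noise_sd=0.1,
        injection_jitter=0.2,
        n_injections_per_source=2,
        frac_unconnected=0.4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_regions=8,
        grid_dims_expr=(10, 8, 8),
        n_genes=10,
        latent_dim=3,
        effect_size=4.0,
        noise_sd=0.0,
        injection_jitter=0.0,
        n_injections_per_source=3,
        frac_unconnected=0.4,
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_data(noiseless_config):
    return generate_dataset(noiseless_config)


def make_dataset(
    n: int, n_genes: int = 2, labels=None, seed: int = 0
) -> SourceTargetDataset:
    """Ad-hoc Source-Target dataset with random features for split/scale tests."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = rng.integers(0, 2, size=n)
    labels = np.asarray(labels, dtype=int)
    return SourceTargetDataset(
        features=rng.normal(size=(n, 2 * n_genes)).astype(np.float32),
        labels=labels,
        source_region=rng.integers(10, 14, size=n),
        target_region=rng.integers(14, 18, size=n),
        source_voxel=np.arange(n),
        target_voxel=np.arange(n) + 1,
        n_genes=n_genes,
    )
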