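import numpy as np
import pytest

from tdgrn import ExpressionDataset, OptimizerConfig, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_optimizer():
    return OptimizerConfig.small()


@pytest.fixture
def toy_dataset(rng):
    """4 genes x 30 time points of smooth random data."""
    values = np.cumsum(rng.normal(0, 0.1, (4, 30)), axis=1) + 0.5
    return ExpressionDataset(
        gene_ids=("gA", "gB", "gC", "gD"), values=values
    )


@pytest.fixture
def default_config():
    return RunConfig()


def random_walk(rng, m, scale=0.15):
    return np.cumsum(rng.normal(0, 1, m)) * scale
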