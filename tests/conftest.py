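"""Shared fixtures: the mini synthetic benchmark, its oracle TM labels,
and one trained mini model.  The heavy fixtures are session-scoped so the
benchmark generation, all-vs-all oracle labelling and the training run
each happen once per test session."""

import numpy as np
import pytest
from hypothesis import settings

from foldvec.model import AggregatorConfig, EncoderConfig
from foldvec.synthetic import generate_benchmark
from foldvec.tmscore import pairwise_tm_table
from foldvec.training import TrainingConfig, train

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

MASTER_SEED = 7
TRAIN_SEED = 1


@pytest.fixture(scope="session")
def mini_benchmark():
    """4 folds x 2 superfamilies x 2 families x 3 members (48 chains)."""
    return generate_benchmark(4, 2, 2, 3, master_seed=MASTER_SEED)


@pytest.fixture(scope="session")
def mini_pairs(mini_benchmark):
    """Oracle tm_max for all 1128 unordered pairs of the mini benchmark."""
    return pairwise_tm_table(mini_benchmark.structures)


@pytest.fixture(scope="session")
def mini_configs():
    return EncoderConfig(), AggregatorConfig.mini_preset()


@pytest.fixture(scope="session")
def trained_mini(mini_benchmark, mini_pairs, mini_configs):
    """A 15-epoch twin-network training run on the mini benchmark."""
    enc, agg = mini_configs
    cfg = TrainingConfig(master_seed=TRAIN_SEED)
    weights, history = train(mini_benchmark, enc, agg, cfg, pairs=mini_pairs)
    return weights, history


@pytest.fixture(scope="session")
def clustered_vectors():
    """10 000 clustered 32-d vectors for retrieval tests."""
    rng = np.random.default_rng(0)
    centers = rng.normal(size=(50, 32))
    return centers[rng.integers(0, 50, 10_000)] + 0.3 * rng.normal(
        size=(10_000, 32))
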