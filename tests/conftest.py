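"""Shared fixtures.

The expensive end-to-end artifacts (three benchmark replicates and the
damage study) are session-scoped so the acceptance tests and any
property checks share one training run per seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import sporeseg as ss
from sporeseg.benchmark import run_benchmark_replicate, run_damage_study

BENCHMARK_SEEDS = (0, 1, 2)


@pytest.fixture(scope="session")
def small_phantom() -> ss.AnnotatedImage:
    """One 128x112 phantom with all 8 classes present."""
    return ss.generate_spore_phantom(ss.PhantomConfig(image_size=(128, 112), seed=7))


@pytest.fixture(scope="session")
def tiny_cnn_config() -> ss.CNNConfig:
    """A narrow encoder (same doubling law, stem width 2) for fast wiring tests."""
    return ss.CNNConfig(
        stem_channels=2,
        block_channels=(4, 8, 16, 32, 64),
        convs_per_block=(1, 1, 1, 1, 1),
        epochs=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def benchmark_replicates() -> list:
    """Three seeded end-to-end runs of the desk benchmark (slow)."""
    return [run_benchmark_replicate(seed) for seed in BENCHMARK_SEEDS]


@pytest.fixture(scope="session")
def damage_study(benchmark_replicates):
    """20 matched intact/damaged pairs, segmented by the seed-0 model."""
    return run_damage_study(benchmark_replicates[0].model, n_pairs=20, seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_pool() -> list:
    return ss.generate_dataset(9, ss.PhantomConfig(image_size=(96, 96)), seed=21)


@pytest.fixture(scope="session")
def tiny_rf_config() -> ss.RFConfig:
    return ss.RFConfig(n_trees=10, features_per_split=5, max_pixels_per_image=30, seed=0)


@pytest.fixture(scope="session")
def tiny_hybrid(tiny_pool, tiny_rf_config):
    """A fast narrow-encoder hybrid trained on 6 small phantoms."""
    cfg = ss.CNNConfig(
        stem_channels=2,
        block_channels=(4, 8, 16, 32, 64),
        convs_per_block=(1, 1, 1, 1, 1),
        epochs=1,
        seed=0,
    )
    model = ss.train_hybrid(tiny_pool[:6], cfg, tiny_rf_config, augment=False)
    return model, cfg, tiny_rf_config
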