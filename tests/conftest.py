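"""Shared fixtures: one standard planted study and cached pretraining runs.

Pretraining is the expensive step, so trained results are cached per
(seed, theta) at session scope and shared by the evaluation, fine-tuning
and acceptance tests.
"""

import numpy as np
import pytest

from contextppi.pipeline import build_study, pretrain_study
from contextppi.synthetic import generate_fixture
from contextppi.training import fixture_config

BASE_SEED = 7


@pytest.fixture(scope="session")
def study():
    """The standard 5-cell-type planted study (marker_fold=10)."""
    return build_study(generate_fixture(BASE_SEED), seed=BASE_SEED)


@pytest.fixture(scope="session")
def tiny_study():
    """A 3-cell-type study for cheap training tests."""
    fx = generate_fixture(
        BASE_SEED + 1, n_cell_types=3, block_size=12, n_pool=8, n_ontology_leaves=6
    )
    return build_study(fx, seed=BASE_SEED + 1)


@pytest.fixture(scope="session")
def trained_cache(study):
    """Lazy cache of pretraining results keyed by (seed, theta)."""
    cache = {}

    def get(seed: int, theta: float = 0.5):
        key = (seed, theta)
        if key not in cache:
            cache[key] = pretrain_study(
                study, seed=seed, config=fixture_config(theta=theta)
            )
        return cache[key]

    return get


@pytest.fixture(scope="session")
def trained(trained_cache):
    """One pretrained run at the default mixing weight."""
    return trained_cache(BASE_SEED, 0.5)


@pytest.fixture(scope="session")
def embedding_space(trained):
    return trained.embedding_space


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
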