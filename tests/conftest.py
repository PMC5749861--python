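import dataclasses
import logging

import numpy as np
import pytest

from lrsslmda.pipeline import Dataset, PipelineConfig, train_and_score
from lrsslmda.synthetic_data import SMALL, generate

logging.getLogger("lrsslmda").setLevel(logging.ERROR)

# moderate optimizer settings used across the suite: identical fixed points,
# fewer iterations than the library default
FAST = PipelineConfig(max_iter=300, tol=1e-5, seed=0)


@pytest.fixture(scope="session")
def small_data():
    """One small synthetic dataset (60 x 40, planted clusters, seed 0)."""
    return generate(SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_data):
    assoc, fs, dags, _ = small_data
    return Dataset(assoc=assoc, fs=fs, dags=dags)


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A fitted model on the small dataset, shared across tests."""
    return train_and_score(small_dataset, FAST)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def tiny_config(**kw):
    return dataclasses.replace(SMALL, **kw)
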