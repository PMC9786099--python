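import numpy as np
import pytest

from igwo.config import OptimizerConfig
from igwo.simulate import FeatureGenSpec, PhantomSpec, make_feature_dataset, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def planted_dataset():
    """Default planted-feature benchmark dataset (seed 0)."""
    return make_feature_dataset(FeatureGenSpec(seed=0))


@pytest.fixture(scope="session")
def phantom():
    """Default 3-disk phantom and its ground-truth mask."""
    return make_phantom(PhantomSpec())


@pytest.fixture
def small_config():
    """Tiny budget for loop-plumbing tests."""
    return OptimizerConfig(population_size=6, iterations=10)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


@pytest.fixture
def sphere_objective():
    return sphere
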