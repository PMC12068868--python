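import numpy as np
import pytest
from hypothesis import settings

from paleopop.datasets import load_thrush_stats, load_thrush_tree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def thrush_stats():
    return load_thrush_stats()


@pytest.fixture(scope="session")
def thrush_tree():
    return load_thrush_tree()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
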