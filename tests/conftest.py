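import numpy as np
import pytest

from varselbench.dataset import Dataset
from varselbench.preprocess import preprocess
from varselbench.synthetic import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset(rng):
    """60 samples, 3 informative + 7 noise columns, low noise."""
    X = rng.standard_normal((60, 10))
    y = 2.0 * X[:, 0] + 1.5 * X[:, 1] - X[:, 2] + rng.normal(scale=0.3, size=60)
    return Dataset(X=X, y=y, names=[f"x{i}" for i in range(10)])


@pytest.fixture(scope="session")
def benchmark_pair():
    """The default synthetic fixture, fully preprocessed (spiked + scaled)."""
    ds, truth = generate(SyntheticSpec(seed=7))
    pair = preprocess(ds, seed=7)
    return pair, truth


def truth_mask_for(pair_train, truth):
    """Ground-truth informative mask aligned with post-preprocessing columns."""
    informative = {f"inf_{i + 1}" for i in range(int(truth.informative_mask.sum()))}
    return np.array([n in informative for n in pair_train.names])
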