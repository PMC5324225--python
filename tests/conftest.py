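import numpy as np
import pytest

from sparselogit import make_dataset


def two_by_two(a: int, b: int, c: int, d: int):
    """2x2 dataset: binary predictor X (1/0) vs outcome Y.

    a = events at X=1, b = non-events at X=1, c = events at X=0,
    d = non-events at X=0.
    """
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    return make_dataset(x[:, None], y, kinds=["binary"], names=("x",))


@pytest.fixture
def complete_separation():
    # level A: 10 events / 0 non-events; level B: 0 / 10
    return two_by_two(10, 0, 0, 10)


@pytest.fixture
def quasi_separation():
    # level A: 10 events / 0 non-events; level B: 2 / 8
    return two_by_two(10, 0, 2, 8)


@pytest.fixture
def balanced_2x2():
    return two_by_two(10, 5, 5, 10)


@pytest.fixture
def random_dataset():
    """Moderate, well-behaved dataset: 2 continuous + 1 binary predictor."""
    rng = np.random.default_rng(42)
    n = 200
    X = np.column_stack(
        [rng.standard_normal(n), rng.standard_normal(n), rng.binomial(1, 0.4, n)]
    )
    eta = -0.5 + 0.8 * X[:, 0] - 0.4 * X[:, 1] + 1.0 * X[:, 2]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    return make_dataset(X, y, kinds=["continuous", "continuous", "binary"])
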