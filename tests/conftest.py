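import numpy as np
import pytest

from kmyouden import BiomarkerSample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sample(rng):
    """A small two-class Gaussian sample with a linear signal."""
    n = 40
    y = np.repeat([1.0, -1.0], n // 2)
    X = rng.standard_normal((n, 3))
    X[y > 0] += [1.0, 0.5, 0.0]
    return BiomarkerSample(X, y)


def random_instance(rng, n=30, m=3, shift=0.8):
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    if not (np.any(y > 0) and np.any(y < 0)):
        y[0] = -y[0]
    X = rng.standard_normal((n, m))
    X[y > 0] += shift
    return BiomarkerSample(X, y)
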