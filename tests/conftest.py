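import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmclust.electrostatics import GridGeometry
from cmclust.matrices import LabeledSquareMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    return GridGeometry(origin=(-6.0, -6.0, -6.0), spacing=(1.5, 1.5, 1.5), shape=(9, 9, 9))


def random_similarity(rng, n, low=-1.0, high=1.0, labels=None):
    """A random symmetric similarity matrix with unit diagonal."""
    v = rng.uniform(low, high, size=(n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 1.0)
    if labels is None:
        labels = tuple(f"p{i}" for i in range(n))
    return LabeledSquareMatrix(labels, v, "similarity")


def random_distance(rng, n, scale=2.0, labels=None):
    v = rng.uniform(0.0, scale, size=(n, n))
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 0.0)
    if labels is None:
        labels = tuple(f"p{i}" for i in range(n))
    return LabeledSquareMatrix(labels, v, "distance")
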