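import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from grasshh.heterogeneity import ValueSample
from grasshh.surfaces import PointCloud


@pytest.fixture
def rng():
    return np.random.default_rng(20210512)  # first survey day of the field season


@pytest.fixture
def plane_cloud(rng):
    """400 random points lying exactly on z = 0.3 x - 0.1 y + 2."""
    x = rng.uniform(0, 10, 400)
    y = rng.uniform(0, 10, 400)
    z = 0.3 * x - 0.1 * y + 2.0
    return PointCloud(np.column_stack([x, y, z]))


def brute_force_rao_q(values):
    """O(N^2) Rao's Q: mean absolute difference over all ordered pairs."""
    x = np.asarray(values, dtype=np.float64)
    return float(np.abs(x[:, None] - x[None, :]).sum() / x.size**2)


def sample(values) -> ValueSample:
    return ValueSample(np.asarray(values, dtype=np.float64))
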