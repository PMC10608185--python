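import numpy as np
import pytest

from hoconn.io_core import TimeSeriesSet, spawn_rng
from hoconn.simulator import SimulationConfig, simulate_benchmark_network


def make_ts(data, labels=None, rsn_map=None):
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = tuple(f"S{i + 1}" for i in range(data.shape[1]))
    return TimeSeriesSet(data=data, labels=tuple(labels), rsn_map=rsn_map)


@pytest.fixture
def rng():
    return spawn_rng(20240917, "tests")


@pytest.fixture
def benchmark_ts():
    return simulate_benchmark_network(SimulationConfig(seed=7))


@pytest.fixture
def random_ts(rng):
    """8 channels with a dense random (PD) covariance, M=400."""
    a = rng.standard_normal((8, 8))
    cov = a @ a.T + 8 * np.eye(8)
    chol = np.linalg.cholesky(cov)
    data = rng.standard_normal((400, 8)) @ chol.T
    return make_ts(data)
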