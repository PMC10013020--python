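import numpy as np
import pytest

import ppmir
from ppmir import EstimatorConfig, EventSeries, PATParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def poisson_pair():
    """Uncoupled unit-rate Poisson pair, N = 300, distinct time origins."""
    x = ppmir.simulate_renewal("exponential", 300, seed=11, rate=1.0)
    y = ppmir.simulate_renewal("exponential", 300, seed=12, rate=1.0, t0=0.37)
    return x, y


@pytest.fixture(scope="session")
def sim2_pair():
    """Strongly coupled heartbeat / pulse-arrival pair (sigma_PAT = 10 ms)."""
    x = ppmir.simulate_hdig(n_events=300, seed=21)
    y = ppmir.simulate_pat_process(x, PATParams(sigma_pat=0.010), seed=22)
    return x, y


@pytest.fixture(scope="session")
def sim2_pair_weak():
    """Weakly coupled pair at the top of the delay-SD grid."""
    x = ppmir.simulate_hdig(n_events=300, seed=31)
    y = ppmir.simulate_pat_process(
        x, PATParams(sigma_pat=0.235), seed=32, on_violation="clip"
    )
    return x, y


@pytest.fixture
def tiny_target():
    return EventSeries([1.0, 2.0, 3.5, 4.0], label="X")


@pytest.fixture
def tiny_source():
    return EventSeries([0.5, 2.6, 3.8], label="Y")


@pytest.fixture(scope="session")
def default_cfg():
    return EstimatorConfig(seed=7)
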