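import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hrvdcan.series import NNSeries

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_nn(intervals_ms, start_s: float = 0.0, contiguous=None) -> NNSeries:
    """NN series with onset times implied by the intervals themselves."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    onsets = start_s + np.concatenate(([0.0], np.cumsum(intervals_ms[:-1]) / 1000.0))
    return NNSeries(intervals_ms, onsets, contiguous)


@pytest.fixture
def white_noise_nn():
    """16-min tachogram of iid Gaussian NN intervals (mean 900, SD 60 ms)."""
    rng = np.random.default_rng(42)
    intervals = 900.0 + 60.0 * rng.standard_normal(1100)
    return make_nn(intervals)


@pytest.fixture
def steady_nn():
    """16-min constant tachogram at 900 ms."""
    return make_nn(np.full(1067, 900.0))
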