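import numpy as np
import pytest

from diybot.timeseries import UniformTimeSeries


def logistic_series(n: int, seed: int = 0, r: float = 3.8) -> np.ndarray:
    """Plain logistic map trajectory with a seeded start in (0.2, 0.8)."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.8)
    out = np.empty(n)
    for i in range(n):
        out[i] = x
        x = r * x * (1 - x)
    return out


@pytest.fixture
def logistic_ts() -> UniformTimeSeries:
    return UniformTimeSeries(logistic_series(600, seed=1), step=1.0, channels=["x"])


@pytest.fixture
def sinusoid_ts() -> UniformTimeSeries:
    t = np.arange(400)
    return UniformTimeSeries(np.sin(2 * np.pi * t / 20), step=1.0, channels=["s"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
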