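import numpy as np
import pytest

from anesgc import Recording, SimConfig, generate_recording


def make_coupled_pair(n: int, c: float, rng: np.random.Generator,
                      rho: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """x2 white noise; x1(t) = c*x2(t-1) + e(t); unit innovation variances.

    The asymptotic GC from x2 to x1 is ln(1 + c^2); optionally the two
    innovations are instantaneously correlated with coefficient rho.
    """
    cov = np.array([[1.0, rho], [rho, 1.0]])
    e = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    x2 = e[:, 1]
    x1 = e[:, 0].copy()
    x1[1:] += c * x2[:-1]
    return x1, x2


def ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    e = rng.normal(size=n + 200)
    x = np.empty(n + 200)
    x[0] = e[0]
    for t in range(1, n + 200):
        x[t] = phi * x[t - 1] + e[t]
    return x[200:]


@pytest.fixture(scope="session")
def short_sim_config() -> SimConfig:
    """A reduced two-state recording: 2-min awake spans, anesthetized span
    long enough for the 5-min post-induction skip plus 100 windows."""
    return SimConfig(durations=(120.0, 620.0, 120.0), seed=11)


@pytest.fixture(scope="session")
def short_recording(short_sim_config):
    return generate_recording(short_sim_config)


@pytest.fixture(scope="session")
def short_ingested(short_recording) -> Recording:
    return Recording(signal=short_recording.signal,
                     labels=short_recording.labels,
                     fs=short_recording.fs,
                     markers=dict(short_recording.markers))
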