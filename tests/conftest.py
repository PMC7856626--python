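import numpy as np
import pytest

from pqxinar.pqx import PQXParams, logsf, pmf


def support_window(params: PQXParams, tail: float = 1e-14) -> np.ndarray:
    """Support points 0..N with P(X > N) < tail, found by doubling."""
    n = 32
    while logsf(n, params) > np.log(tail):
        n *= 2
        if n > 2**22:  # pragma: no cover - guards runaway parameters
            raise RuntimeError("support window blew up")
    return np.arange(n + 1)


def truncated_moments(params: PQXParams) -> dict:
    """Independent oracle: moments from direct summation of the pmf."""
    x = support_window(params)
    p = pmf(x, params)
    m = float(np.sum(x * p))
    c2 = float(np.sum((x - m) ** 2 * p))
    c3 = float(np.sum((x - m) ** 3 * p))
    c4 = float(np.sum((x - m) ** 4 * p))
    return {
        "mean": m,
        "variance": c2,
        "dispersion_index": c2 / m,
        "skewness": c3 / c2**1.5,
        "kurtosis": c4 / c2**2,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_params(rng):
    """A spread of admissible (alpha, theta) pairs across the parameter region."""
    alphas = rng.uniform(0.05, 20.0, size=40)
    thetas = rng.uniform(0.1, 8.0, size=40)
    return [PQXParams(float(a), float(t)) for a, t in zip(alphas, thetas)]
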