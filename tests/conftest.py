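import numpy as np
import pytest

from glidertex import ensemble_analysis as ea
from glidertex import glider_stats as gs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def correlated_cov(rng):
    """A well-conditioned, correlated 9x9 covariance for ensemble tests."""
    A = 0.1 * rng.standard_normal((9, 9))
    return A @ A.T + np.diag(np.linspace(1.0, 0.2, 9))


def random_feasible_coords(rng, n, scale=0.4):
    """Rejection-sample coordinate vectors with feasible window distributions."""
    out = []
    while len(out) < n:
        v = rng.uniform(-scale, scale, 10)
        try:
            gs.histogram_from_coords(v)
        except gs.InfeasibleCoordinatesError:
            continue
        out.append(v)
    return out


@pytest.fixture(scope="session")
def matched_pair(correlated_cov):
    """An image ensemble summary and a psychophysical (sens, Q) that match it.

    Under the variance-is-salience hypothesis the isodiscrimination
    quadratic Q is proportional to the coordinate covariance, and the
    sensitivities are proportional to the standard deviations.
    """
    cov = correlated_cov
    std = np.sqrt(np.diag(cov))
    Q = 4.0 * cov
    sens = np.sqrt(np.diag(Q))
    return std, cov, sens, Q
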