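import numpy as np
import pytest

from lltmval import (
    ResponseMatrix,
    simulate_rasch_data,
    spread_difficulties,
    synthetic_qmatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_rasch_data():
    """A 6-item Rasch dataset small enough for enumeration oracles."""
    rng = np.random.default_rng(7)
    beta = np.array([-1.2, -0.6, -0.1, 0.3, 0.7, 0.9])
    return simulate_rasch_data(beta, 200, rng=rng)


@pytest.fixture(scope="session")
def medium_rasch_data():
    """A 10-item dataset for scenario-level tests."""
    rng = np.random.default_rng(11)
    return simulate_rasch_data(spread_difficulties(10), 250, rng=rng)


@pytest.fixture(scope="session")
def theoretical_q_12():
    """A fixed identifiable 12x4 Q-matrix used as a 'theoretical' matrix."""
    return synthetic_qmatrix(12, 4, prop_ones=0.4, seed=99)


@pytest.fixture(scope="session")
def rasch_data_12():
    rng = np.random.default_rng(13)
    return simulate_rasch_data(spread_difficulties(12), 250, rng=rng)


@pytest.fixture(scope="session")
def theoretical_q_17():
    """A fixed identifiable 17x5 Q-matrix (reading-test-sized)."""
    return synthetic_qmatrix(17, 5, prop_ones=0.35, seed=23)


@pytest.fixture(scope="session")
def lltm_data_17(theoretical_q_17):
    """Responses whose difficulties truly follow the 17x5 Q-matrix."""
    from lltmval import simulate_lltm_data

    rng = np.random.default_rng(17)
    eta = np.linspace(-1.4, 1.4, 5)
    return simulate_lltm_data(theoretical_q_17, eta, 300, rng=rng)


def make_two_item_data(n10=6, n01=2, n11=3, n00=2) -> ResponseMatrix:
    rows = [[1, 0]] * n10 + [[0, 1]] * n01 + [[1, 1]] * n11 + [[0, 0]] * n00
    return ResponseMatrix(data=np.array(rows))
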