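import numpy as np
import pytest

from schloegl import SchloeglParams, stationary_distribution


@pytest.fixture(scope="session")
def params():
    """Standard bistable working point: b = 4, Ω = 100."""
    return SchloeglParams()


@pytest.fixture(scope="session")
def params_b365():
    """Near the critical driving, Ω = 100."""
    return SchloeglParams(b_conc=3.65)


@pytest.fixture(scope="session")
def params_o10():
    """Small system (Ω = 10) at b = 4 for simulation cross-checks."""
    return SchloeglParams(omega=10.0)


@pytest.fixture(scope="session")
def params_eq():
    """Detailed-balance driving b0 = 1/6."""
    return SchloeglParams(b_conc=1.0 / 6.0)


@pytest.fixture(scope="session")
def stat_o10(params_o10):
    return stationary_distribution(params_o10)


@pytest.fixture(scope="session")
def stat_b365(params_b365):
    return stationary_distribution(params_b365)


@pytest.fixture(scope="session")
def x_grid():
    return np.linspace(1e-3, 6.0, 800)
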