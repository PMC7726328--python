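import numpy as np
import pytest

from txtlkit.circuits import builtin_circuit


@pytest.fixture(scope="session")
def c1():
    """Built-in sigma70 -> deGFP circuit with its mean parameter estimates."""
    return builtin_circuit("C1")


@pytest.fixture(scope="session")
def c2():
    """Built-in negative-feedback circuit with its mean parameter estimates."""
    return builtin_circuit("C2")


@pytest.fixture(scope="session")
def c1_trajectory(c1):
    from txtlkit.simulation import simulate

    spec, _ = c1
    return simulate(spec, t_end=16.0)


@pytest.fixture(scope="session")
def c2_trajectory(c2):
    from txtlkit.simulation import simulate

    spec, _ = c2
    return simulate(spec, t_end=16.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
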