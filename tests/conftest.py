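import numpy as np
import pytest

from sdecoeff.sde import (InitialDistribution, PathEnsemble, TimeGrid,
                          euler_maruyama_simulate, make_benchmark_problem)


@pytest.fixture(scope="session")
def ou_small():
    """500-path OU ensemble on [0, 5] with 100 points (paper parameters)."""
    problem = make_benchmark_problem("OU", grid=TimeGrid.regular(0.0, 5.0, 100))
    return euler_maruyama_simulate(problem, 500, noise=101)


@pytest.fixture(scope="session")
def ou_problem_small():
    return make_benchmark_problem("OU", grid=TimeGrid.regular(0.0, 5.0, 100))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def toy_grid():
    return TimeGrid.regular(0.0, 1.0, 5)


def make_ensemble(values, t0=0.0, t1=1.0):
    values = np.asarray(values, dtype=np.float64)
    return PathEnsemble(values=values, grid=TimeGrid.regular(t0, t1, values.shape[1]))
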