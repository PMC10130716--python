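"""Shared fixtures.

The expensive Monte Carlo runs (the 10^4-particle arrival table and the
matching time-free splitting counts for the three-receptor cell) are
session-scoped so that the simulator tests and the acceptance checks share
one realization.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", database=None, derandomize=True,
                          deadline=None)
settings.load_profile("suite")

from gradsense import (
    SourceSpec,
    simulate_arrivals,
    simulate_splitting,
    three_receptor_config,
)

TABLE1_SEED = 20230426


@pytest.fixture(scope="session")
def fixture_config():
    """Three-receptor validation cell at eps = 0.1."""
    return three_receptor_config(0.1)


@pytest.fixture(scope="session")
def fixture_source():
    return SourceSpec(R=2.0, theta0=0.0, D=1.0)


@pytest.fixture(scope="session")
def table1_arrivals(fixture_config, fixture_source):
    """10^4 time-resolved arrivals, censored at t = 10^3."""
    return simulate_arrivals(10_000, fixture_config, fixture_source,
                             T_max=1e3, seed=TABLE1_SEED)


@pytest.fixture(scope="session")
def table1_splitting(fixture_config, fixture_source):
    """10^4 time-free splitting counts (the t = infinity row)."""
    return simulate_splitting(10_000, fixture_config, fixture_source,
                              seed=TABLE1_SEED + 1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def first_arrival_angles():
    """Angles of the first of M = 10^4 arrivals, 1000 replicates.

    All-absorbing cell, source at R = 2: the reference experiment for the
    extreme-value angle statistics.
    """
    from gradsense import extreme_params, simulate_absorbing_circle

    M, reps = 10_000, 1000
    p = extreme_params(M, 2.0, np.inf)
    tab = simulate_absorbing_circle(
        M * reps, SourceSpec(R=2.0), T_max=p.b_M + 25 * p.a_M, seed=4242
    )
    tt = np.where(tab.censored, np.inf, tab.times).reshape(reps, M)
    aa = tab.angles.reshape(reps, M)
    return aa[np.arange(reps), np.argmin(tt, axis=1)]
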