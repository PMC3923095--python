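"""Shared fixtures: simulated studies and fits reused across test modules.

Session-scoped fixtures keep the expensive PQL fits to a handful per run.
The "default" study is the published 8-hospital 2004-2008 design at the
published parameter values; the "small" study is a balanced 4-hospital,
3-year network used where fit speed matters more than realism.
"""

import numpy as np
import pytest

from hliest import (
    FitControl,
    SimulationConfig,
    build_design,
    fit_pql,
    simulate_network,
)

SEED = 20040


def small_config(**overrides) -> SimulationConfig:
    kwargs = dict(n_hospitals=4, years=(2005, 2006, 2007))
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_network(seed=SEED)


@pytest.fixture(scope="session")
def default_design(default_dataset):
    return build_design(default_dataset.counts)


@pytest.fixture(scope="session")
def default_fit(default_design):
    return fit_pql(default_design)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_network(small_config(), seed=SEED + 1)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    return fit_pql(build_design(small_dataset.counts))


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
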