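"""Shared fixtures.

The expensive twin-experiment runs are session-scoped and lazily built, so
each assimilation is executed exactly once no matter how many tests read
its metrics.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuroassim.assimilate import (TwinConfig, crippled_alpha_experiment,
                                   cross_cell_experiment, fixed_ion_comparison,
                                   gating_tracking_experiment,
                                   microenvironment_experiment)
from neuroassim.biophysics import CellParams, MicroenvParams, resting_state
from neuroassim.simulate import seizure_fixture, spiking_pc_fixture

SEED = 1


@pytest.fixture(scope="session")
def rest_state():
    return resting_state(CellParams(), MicroenvParams(), polish=False)


@pytest.fixture(scope="session")
def rest_state_polished():
    return resting_state(CellParams(), MicroenvParams(), polish=True)


@pytest.fixture(scope="session")
def spiking_fixture():
    return spiking_pc_fixture(seed=SEED)


@pytest.fixture(scope="session")
def seizure_fixture_data():
    return seizure_fixture(seed=SEED)


@pytest.fixture(scope="session")
def gating_report():
    return gating_tracking_experiment(TwinConfig(seed=SEED))


@pytest.fixture(scope="session")
def crippled_report():
    return crippled_alpha_experiment(
        TwinConfig(seed=SEED, tracked_parameters=("alpha_m",)))


@pytest.fixture(scope="session")
def microenv_report():
    return microenvironment_experiment(TwinConfig(seed=SEED))


@pytest.fixture(scope="session")
def aic_runs():
    return [fixed_ion_comparison(TwinConfig(seed=s)) for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def cross_cell_reports():
    return {obs: cross_cell_experiment(TwinConfig(seed=SEED), observe=obs)
            for obs in ("pc", "in")}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
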