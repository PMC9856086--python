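"""Shared fixtures: generated test systems and completed repair runs.

The expensive end-to-end repair runs are session-scoped so the workflow,
chirality and acceptance tests all share one run per configuration.
"""

import numpy as np
import pytest

from ringfree import fixtures as fx
from ringfree.charmm_io import RunConfig
from ringfree.energy_min import EnergyModel, minimize
from ringfree.workflow import run_lbe


@pytest.fixture(scope="session")
def benzene_bundle():
    return fx.make_pierced_benzene_ethane()


@pytest.fixture(scope="session")
def polymer_bundle():
    return fx.make_toy_polymer(5, 3, seed=7)


@pytest.fixture(scope="session")
def clean_bundle():
    return fx.make_toy_polymer(3, 0, seed=0)


@pytest.fixture(scope="session")
def glyco_bundle():
    return fx.make_glyco_peptide_toy(seed=0)


@pytest.fixture(scope="session")
def benzene_plain_min(benzene_bundle):
    """500 plain minimization steps on the pierced fixture (no biases)."""
    return minimize(
        benzene_bundle.system, benzene_bundle.params, EnergyModel(), steps=500
    )


@pytest.fixture(scope="session")
def benzene_run(benzene_bundle):
    return run_lbe(RunConfig(seed=1), system=benzene_bundle.system,
                   params=benzene_bundle.params)


@pytest.fixture(scope="session")
def polymer_run(polymer_bundle):
    return run_lbe(RunConfig(seed=1), system=polymer_bundle.system,
                   params=polymer_bundle.params)


@pytest.fixture(scope="session")
def clean_run(clean_bundle):
    return run_lbe(RunConfig(seed=1), system=clean_bundle.system,
                   params=clean_bundle.params)


@pytest.fixture(scope="session")
def glyco_run(glyco_bundle):
    return run_lbe(RunConfig(seed=1), system=glyco_bundle.system,
                   params=glyco_bundle.params)


@pytest.fixture(scope="session")
def strained_glyco_bundle():
    return fx.make_strained_glyco_toy(seed=0)


@pytest.fixture(scope="session")
def strained_run_restrained(strained_glyco_bundle):
    return run_lbe(RunConfig(seed=1), system=strained_glyco_bundle.system,
                   params=strained_glyco_bundle.params)


@pytest.fixture(scope="session")
def strained_run_unrestrained(strained_glyco_bundle):
    return run_lbe(RunConfig(seed=1, chirality=False),
                   system=strained_glyco_bundle.system,
                   params=strained_glyco_bundle.params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
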