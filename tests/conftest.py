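"""Shared fixtures: small simulated sessions and cohorts, built at test time."""

import numpy as np
import pytest

from avcausal import synthetic_data as sd
from avcausal.core_model import ObserverParams


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_session():
    return sd.make_session(sd.SessionDesign(shuffle_seed=7))


@pytest.fixture(scope="session")
def m8_params():
    return ObserverParams.from_dict(dict(sd.DEFAULT_M8_PARAMS))


@pytest.fixture(scope="session")
def m8_observer_trials(default_session, m8_params):
    """One observer's 525-trial session simulated from the hybrid model."""
    rng = np.random.default_rng(2024)
    return sd.simulate_observer(m8_params, default_session, rng, subject="S001")


@pytest.fixture(scope="session")
def m8_cohort():
    """A small hybrid-model cohort with central visual / peripheral auditory bias."""
    pop = sd.PopulationSpec(n_subjects=12, master_seed=77)
    trials, truth = sd.simulate_population(pop)
    return trials, truth
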