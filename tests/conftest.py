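"""Shared fixtures: configurations and small synthetic trials.

Everything is generated programmatically at test time; expensive
artifacts (trial datasets, fits) are session-scoped.
"""

import dataclasses

import numpy as np
import pytest

from oralpax.params import default_config
from oralpax.synthetic import TrialDesignSpec, generate_trial


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def pac(config):
    return config.paclitaxel


@pytest.fixture(scope="session")
def physio(config):
    return config.physio


@pytest.fixture(scope="session")
def no_bov_config(config):
    """Truth without between-occasion variability (single-occasion designs)."""
    re = dataclasses.replace(config.random_effects, bov_cv_rf_gut=0.0)
    return config.replace(random_effects=re)


@pytest.fixture(scope="session")
def small_trial(config):
    """Day-1 LDM trial, 8 subjects, PK only (with BSV + BOV)."""
    spec = TrialDesignSpec(template="study3", n_subjects=8, n_days=1,
                           pd_sampling_days=())
    return generate_trial(spec, config, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
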