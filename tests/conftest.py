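"""Shared fixtures: a default generative observer, designs and cached fits.

Expensive artefacts (full synthetic datasets, multistart fits) are
session-scoped so that parameter-recovery, method-agreement and reporting
tests share one computation.
"""

import numpy as np
import pytest

import speedprior as sp
from speedprior.fitting import FitConfig, fit_full_likelihood, fit_model, predict_table


@pytest.fixture(scope="session")
def observer():
    """Default Thompson-direction observer (negative prior slopes)."""
    return sp.ObserverSpec()


@pytest.fixture(scope="session")
def design():
    return sp.build_design()


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture(scope="session")
def dataset(observer, design):
    """One full default-design synthetic dataset (300 staircases)."""
    return sp.generate_dataset(observer, design, master_seed=11)


@pytest.fixture(scope="session")
def pse_table(dataset):
    return sp.pse_summary(dataset)


@pytest.fixture(scope="session")
def noise_free_table(observer, design, fit_config):
    """Model-predicted PSE table with no simulation noise."""
    return predict_table(observer, design.conditions, fit_config)


@pytest.fixture(scope="session")
def noise_free_fit(noise_free_table, fit_config):
    """Self-consistency fit: the model refit to its own noise-free predictions."""
    return fit_model(noise_free_table, fit_config)


@pytest.fixture(scope="session")
def recovery_fit(pse_table, fit_config):
    """Fast PSE-variance fit to the noisy synthetic dataset."""
    return fit_model(pse_table, fit_config)


@pytest.fixture(scope="session")
def full_likelihood_fit(dataset, fit_config):
    """Trial-level maximum-likelihood fit to the same synthetic dataset."""
    trials = sp.experiment.trials_to_frame(dataset)
    return fit_full_likelihood(trials, fit_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
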