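"""Shared fixtures: calibrated models and one pair of synthetic cohorts.

Session-scoped so the (deterministic) calibration and maximum-likelihood
fits run once for the whole suite.
"""

import pytest

import menopredict as mp


@pytest.fixture(scope="session")
def gen_config():
    """Calibrated default generating parameters (fixed seed)."""
    return mp.default_generating_params(seed=7)


@pytest.fixture(scope="session")
def true_rm(gen_config):
    return gen_config.regression


@pytest.fixture(scope="session")
def true_tm(gen_config):
    return gen_config.threshold_model


@pytest.fixture(scope="session")
def amh_cohort(gen_config):
    return mp.generate_amh_cohort(gen_config)


@pytest.fixture(scope="session")
def meno_cohort(gen_config):
    return mp.generate_menopause_cohort(gen_config)


@pytest.fixture(scope="session")
def fitted_rm(amh_cohort):
    return mp.fit_amh_regression(amh_cohort)


@pytest.fixture(scope="session")
def fitted_tm(meno_cohort, fitted_rm):
    return mp.fit_threshold_model(meno_cohort, fitted_rm)
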