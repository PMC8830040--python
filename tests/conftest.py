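"""Shared fixtures: generated datasets and fits reused across test modules."""

import numpy as np
import pytest

from digoxinpk import (CohortConfig, final_digoxin_model, fit_population,
                       generate_dataset)
from digoxinpk.nlme import FlatData


@pytest.fixture(scope="session")
def final_model():
    return final_digoxin_model()


@pytest.fixture(scope="session")
def small_dataset(final_model):
    """50-patient cohort under the final model (fast shared fixture)."""
    return generate_dataset(final_model, CohortConfig(n_patients=50), seed=123)


@pytest.fixture(scope="session")
def small_flat(small_dataset):
    return FlatData(small_dataset)


@pytest.fixture(scope="session")
def study_dataset(final_model):
    """Study-scale cohort: 391 patients, ~3465 usable troughs."""
    return generate_dataset(final_model, CohortConfig(), seed=2024)


@pytest.fixture(scope="session")
def study_fit(final_model, study_dataset):
    """Final-model refit on the study-scale synthetic dataset."""
    fit = fit_population(final_model, study_dataset)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def tiny_dataset(final_model):
    """5-patient fixture for quadrature checks."""
    return generate_dataset(final_model, CohortConfig(n_patients=5), seed=7)
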