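"""Shared fixtures: small synthetic cohorts and likelihood-ready datasets."""

import numpy as np
import pandas as pd
import pytest

import prepmarkov as pm


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down cohort with the default covariate mix and truth."""
    return pm.CohortSpec(n_subjects=120, n_days=90)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return pm.generate_cohort(small_spec, seed=20240917)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort.to_dataset()


@pytest.fixture(scope="session")
def nocov_spec():
    """Persistent chain, no covariates, moderate between-subject spread."""
    params = pm.MarkovParams(theta1=-1.0, theta2=-2.2, omega_sq=(0.5, 0.5))
    return pm.CohortSpec(n_subjects=80, n_days=90, prevalences={},
                         multinomials={}, true_params=params)


@pytest.fixture(scope="session")
def nocov_dataset(nocov_spec):
    return pm.generate_cohort(nocov_spec, seed=11).to_dataset()


@pytest.fixture(scope="session")
def nocov_markov_fit(nocov_dataset):
    return pm.fit(nocov_dataset)


@pytest.fixture(scope="session")
def nocov_bernoulli_fit(nocov_dataset):
    return pm.fit_bernoulli(nocov_dataset)


def series_of(states, subject_id="S1"):
    import datetime
    return pm.AdherenceSeries(subject_id, datetime.date(2015, 1, 1),
                              np.asarray(states, dtype=np.int8))


@pytest.fixture(scope="session")
def make_series():
    """Stateless factory, session-scoped so hypothesis can reuse it."""
    return series_of
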