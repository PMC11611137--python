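"""Shared fixtures: one response surface, one six-study synthetic cohort and
one desk-scale posterior fit reused across the suite (expensive pieces are
session-scoped; summary-likelihood members are cached process-wide)."""

import numpy as np
import pytest

from aawt.constitutive import build_response_surface
from aawt.hierarchical import build_model, sample_posterior
from aawt.synthetic import generate_cohort, six_study_design

COHORT_SEED = 11
FIT_SEED = 3
TRUTH = {"c": 5.0, "k": 20.0, "mu_pop": 0.85, "sigma_pop": 0.26, "sigma_pat": 0.18}


@pytest.fixture(scope="session")
def surface():
    return build_response_surface()


@pytest.fixture(scope="session")
def six_cohort():
    samples, summaries, truth = generate_cohort(six_study_design(seed=COHORT_SEED))
    return samples, summaries, truth


@pytest.fixture(scope="session")
def six_model(surface, six_cohort):
    samples, summaries, _ = six_cohort
    return build_model(samples, summaries, surface)


@pytest.fixture(scope="session")
def six_fit(six_model):
    return sample_posterior(six_model, chains=4, draws=2000, seed=FIT_SEED)
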