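"""Shared fixtures: small synthetic datasets and configurations."""

import dataclasses

import numpy as np
import pytest

from vwmprecision.mixture import FitConfig, MixtureParams, TrialGeometry, simulate_responses
from vwmprecision.simulate import CohortConfig, generate_cohort, generate_trials


@pytest.fixture(scope="session")
def fast_fit_config():
    """EM settings with fewer restarts, for speed in non-recovery tests."""
    return FitConfig(n_random_restarts=3)


@pytest.fixture(scope="session")
def small_cohort_config():
    """A reduced cohort for end-to-end tests that do not need study scale."""
    return dataclasses.replace(CohortConfig(), n_participants=15, seed=11)


def make_geometries(n, m=2, seed=0):
    """Response-less trial geometries on the doubled circle."""
    rng = np.random.default_rng(seed)
    geoms = []
    for _ in range(n):
        target = float(rng.uniform(0.0, 2.0 * np.pi))
        nontargets = tuple(float(x) for x in rng.uniform(0.0, 2.0 * np.pi, size=m))
        geoms.append(TrialGeometry(target=target, nontargets=nontargets))
    return geoms


def simulate_dataset(params: MixtureParams, n, m=2, seed=0):
    """Geometries plus responses drawn from the mixture."""
    return simulate_responses(params, make_geometries(n, m=m, seed=seed), seed=seed + 1)


@pytest.fixture(scope="session")
def one_participant_trials():
    """One default-config participant's full session."""
    config = CohortConfig(seed=5)
    profile = generate_cohort(config)[0]
    return generate_trials(profile, config)
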