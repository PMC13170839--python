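"""Shared fixtures: phantom cohorts and feature tables are expensive, so
they are simulated once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from synthrad.data_io import Modality
from synthrad.phantom import PhantomConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort50():
    """50-case noisy cohort for class-separation and feature statistics."""
    return simulate_cohort(PhantomConfig(n_cases=50, seed=21))


@pytest.fixture(scope="session")
def cohort50_features_b0(cohort50):
    """526-feature table of the DWI b=0 modality for the 50-case cohort."""
    from synthrad.radiomics import feature_table

    return feature_table(cohort50, Modality.DWI_b0)


@pytest.fixture(scope="session")
def noiseless_case():
    from synthrad.phantom import simulate_case

    return simulate_case(PhantomConfig(n_cases=2, noise_sigma=0.0, seed=9), 0)


@pytest.fixture(scope="session")
def small_case():
    from synthrad.phantom import simulate_case

    return simulate_case(PhantomConfig(n_cases=2, seed=4), 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
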