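"""Shared fixtures: small parameter sets and simulated datasets."""

import numpy as np
import pytest

from bivop import (FitConfig, ModelSpec, Parameters, recovery_truth_fixture,
                   simulate_dataset)


@pytest.fixture(scope="session")
def toy_params():
    """No-covariate parameter set with distinct thresholds per equation."""
    return Parameters(
        beta=(np.array([0.3]), np.array([-0.1])),
        thresholds=(np.array([0.0, 0.6, 1.5]), np.array([0.0, 0.5, 1.3])),
        rho=0.244,
    )


@pytest.fixture(scope="session")
def toy_spec():
    return ModelSpec(covariates=((), ()))


@pytest.fixture(scope="session")
def small_recovery_data():
    """2,000 crashes simulated from the compact published-truth fixture."""
    spec, params, scheme = recovery_truth_fixture()
    df, records, manifest = simulate_dataset(2000, spec, params, scheme,
                                             seed=11)
    return spec, params, scheme, df, records, manifest


@pytest.fixture(scope="session")
def fast_config():
    """Small-R configuration for quick fits in unit tests."""
    return FitConfig(R=40, seed=5, compute_se=True)
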