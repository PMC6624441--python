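import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hblater import (
    ModelConfig,
    SamplerConfig,
    make_recovery_fixture,
    make_study_fixture,
    sample_posterior,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_fit():
    """Window-free simulated study (15 persons x 150 trials/cell) and its fit.

    Default sampler settings (6 chains x 2,000 iterations, 1,000 burn-in);
    shared across recovery, convergence and PPC-calibration tests.
    """
    prepared, truth = make_recovery_fixture(seed=3)
    draws = sample_posterior(prepared, ModelConfig(), SamplerConfig(seed=1))
    return prepared, truth, draws


@pytest.fixture(scope="session")
def study_fit():
    """Full emulated study (17 persons x 750 trials/session, window on) + fit."""
    prepared, truth = make_study_fixture(seed=11)
    draws = sample_posterior(prepared, ModelConfig(), SamplerConfig(seed=5))
    return prepared, truth, draws


@pytest.fixture(scope="session")
def small_fit():
    """Tiny fit for interface-level tests (shape, export, reproducibility)."""
    prepared, truth = make_recovery_fixture(seed=42, n_persons=5, trials_per_cell=40)
    draws = sample_posterior(
        prepared,
        ModelConfig(),
        SamplerConfig(n_chains=2, n_iterations=300, n_burnin=150, seed=7),
    )
    return prepared, truth, draws
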