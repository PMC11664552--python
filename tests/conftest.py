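import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leaflim.leaf_exchange import CalibrationResult
from leaflim.synthetic import DEFAULT_NOISE, ExperimentConfig, TrueResponseSet, generate_dataset

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truth():
    return TrueResponseSet.potato_defaults()


@pytest.fixture(scope="session")
def noise_free_dataset(truth):
    """One synthetic drought experiment without any measurement scatter."""
    cfg = ExperimentConfig(seed=11, noise={})
    return generate_dataset(cfg, truth)


@pytest.fixture(scope="session")
def noisy_dataset(truth):
    """One synthetic experiment at the calibrated default scatter levels."""
    cfg = ExperimentConfig(seed=11, noise=dict(DEFAULT_NOISE))
    return generate_dataset(cfg, truth)


@pytest.fixture(scope="session")
def exact_calibration():
    """Calibration with the reference absorptance-partitioning product."""
    return CalibrationResult(k_slope=0.1825, alpha_beta=0.73, sd=0.0, n_points=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
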