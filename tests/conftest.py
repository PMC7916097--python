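import numpy as np
import pytest

from toxbridge import ComparisonConfig, GridSpec, bundled_dataset


@pytest.fixture(scope="session")
def synthetic_pair():
    """Caucasian vs Synthetic-1 Japanese calibration pair."""
    return bundled_dataset("synthetic1")


@pytest.fixture(scope="session")
def synthetic_config():
    """Settings used for the synthetic calibration sets."""
    return ComparisonConfig(tau=0.3, reference_dose=400.0)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced Monte-Carlo budget for tests that only exercise contracts."""
    return ComparisonConfig(
        tau=0.3,
        reference_dose=400.0,
        n_samples=20_000,
        grid_spec=GridSpec(n_points=150),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210209)
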