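import numpy as np
import pytest

from fedcox import SurvivalDataset, generate_synthetic_survival

BETA4 = np.array([0.1, -0.1, 0.05, -0.05])


@pytest.fixture(scope="session")
def small_dataset() -> SurvivalDataset:
    """Seeded integer-coded dataset, N=60, M=4."""
    return generate_synthetic_survival(60, 4, BETA4, seed=21)


@pytest.fixture(scope="session")
def medium_dataset() -> SurvivalDataset:
    """Seeded integer-coded dataset, N=100, M=4 (comparison-experiment scale)."""
    return generate_synthetic_survival(100, 4, BETA4, seed=7)


@pytest.fixture
def tiny_tied_dataset() -> SurvivalDataset:
    """Hand-enumerable dataset with a tied event time and one censored subject."""
    return SurvivalDataset(times=np.array([2.0, 2.0, 5.0]),
                           events=np.array([1, 1, 0]),
                           covariates=np.array([[1.0], [2.0], [3.0]]),
                           feature_names=("x1",))
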