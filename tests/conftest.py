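import numpy as np
import pytest

from psnquant.synthetic import default_testing_spec, default_training_spec, sample_cohort
from psnquant.types import CTVolume, NoduleMask


@pytest.fixture(scope="session")
def training_spec():
    return default_training_spec()


@pytest.fixture(scope="session")
def testing_spec():
    return default_testing_spec()


@pytest.fixture(scope="session")
def training_cohort(training_spec):
    """One fixed draw of the 239-nodule training cohort."""
    return sample_cohort(training_spec, seed=0)


@pytest.fixture(scope="session")
def testing_cohort(testing_spec):
    return sample_cohort(testing_spec, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_volume_mask():
    """A 2x2x2 grid with known HU values, fully masked."""
    values = np.array(
        [[[-600.0, -500.0], [-400.0, -300.0]], [[-200.0, -100.0], [0.0, 100.0]]]
    )
    return CTVolume(values, (1.0, 1.0, 1.0)), NoduleMask(np.ones((2, 2, 2), bool))
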