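import numpy as np
import pytest

from imugait.io import SensorSelection
from imugait.preprocess import assemble_dataset
from imugait.synth import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects x 1 repetition/task = 21 recordings; fast to simulate."""
    return simulate_cohort(CohortConfig(n_subjects=3, repetitions_per_task=1,
                                        seed=42))


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return assemble_dataset(small_cohort, SensorSelection())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
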