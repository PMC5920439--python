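import numpy as np
import pytest

from psokm import CohortConfig, Dataset, Subject, generate_cohort


@pytest.fixture
def three_subjects() -> Dataset:
    return Dataset(
        [
            Subject(id="a", age=35, weight=80, height=1.80, rter=40, rtir=35, lter=45, ltir=38),
            Subject(id="b", age=25, weight=55, height=1.65, rter=15, rtir=30, lter=50, ltir=70),
            Subject(id="c", age=25, weight=75, height=1.78, rter=66, rtir=20, lter=25, ltir=33),
        ]
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default 484-subject synthetic cohort plus its generating labels."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
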