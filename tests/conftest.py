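import numpy as np
import pytest

from bcgtx.params import default_parameters, default_schedule
from bcgtx.synthetic import GroundTruth, generate_cohort


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 noise-free patients from two smoking-distinct groups (fast to simulate)."""
    truth = GroundTruth(
        effects={"smoking": {"smoker": {"lambda_": 1.4}}},
        sigma=0.0,
        personalize_capacity=False,
    )
    return generate_cohort(truth, 12, seed=99)
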