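import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from antbridge.params import BehaviorParams, DEFAULT_PARAMS
from antbridge.synthetic import generate_removal_experiment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params() -> BehaviorParams:
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def removal_dataset():
    """One seeded removal experiment shared across recovery tests.

    Traffic varies across episodes (uniform 0.25-4 ants/s) so that both
    slopes of the join sigmoid are identified; 5000 logged arrivals.
    """
    return generate_removal_experiment(
        lambda_range=(0.25, 4.0), n_events=5000, seed=11)
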