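"""Shared fixtures and deterministic hypothesis configuration."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_motion():
    """A noise-free contralateral-shoulder motion at 100 Hz."""
    from limbkin import Task, default_task, generate_task_motion

    return generate_task_motion(default_task(Task.CONTRALATERAL_SHOULDER),
                                fs=100.0, seed=7, variability_sd=0.0)


@pytest.fixture(scope="session")
def default_anthro():
    from limbkin import Anthropometry

    return Anthropometry()


@pytest.fixture(scope="session")
def quiet_noise():
    """A noise model with every imperfection switched off."""
    from limbkin import NoiseModel

    return NoiseModel(seed=3)
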