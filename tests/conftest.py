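"""Shared fixtures for the cmjkit test suite."""

import numpy as np
import pytest
from hypothesis import settings

from cmjkit import SyntheticJumpSpec, simulate_cmj

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One noise-free simulated jump with default conditions."""
    return simulate_cmj(SyntheticJumpSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_tset(landmark_z, n=4, fs=100.0, x=0.1):
    """Trajectory set with constant coordinates: landmark name -> z height."""
    from cmjkit import LandmarkTrajectorySet

    lm = {
        name: np.column_stack([np.full(n, x), np.full(n, z)])
        for name, z in landmark_z.items()
    }
    return LandmarkTrajectorySet(sampling_rate_hz=fs, landmarks=lm)
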