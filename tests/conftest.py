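import numpy as np
import pytest

from oisflow import (
    AcquisitionConfig,
    GroundTruthHemodynamics,
    OpticalModel,
    StimulusProtocol,
)


@pytest.fixture(scope="session")
def optics() -> OpticalModel:
    return OpticalModel.default()


@pytest.fixture
def tiny_protocol() -> StimulusProtocol:
    return StimulusProtocol(n_blocks=3)


@pytest.fixture
def tiny_config() -> AcquisitionConfig:
    """Desk-scale acquisition for fast unit tests."""
    return AcquisitionConfig(
        image_shape=(48, 48), baseline_duration=15.0, post_duration=5.0
    )


@pytest.fixture
def tiny_truth() -> GroundTruthHemodynamics:
    return GroundTruthHemodynamics.control_offspring(
        activation_radius=8.0, edge_sigma=2.0
    )


@pytest.fixture
def aligned_tiny_config(tiny_config) -> AcquisitionConfig:
    """Same geometry but with simultaneous channel sampling, for tests of
    algebraic exactness that must not see interleaving lags."""
    import dataclasses

    return dataclasses.replace(tiny_config, simultaneous_channels=True)


def rel_err(a, b):
    return np.abs(np.asarray(a) - np.asarray(b)) / np.abs(b)
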