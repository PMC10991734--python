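import numpy as np
import pytest

from osseodic.geometry import SpecimenGeometry
from osseodic.simulate import (
    GroundTruthKinematics,
    NoiseModel,
    SpecimenSpec,
)


@pytest.fixture
def small_geometry() -> SpecimenGeometry:
    """Default specimen with a coarse 400-node bone grid (fast pose work)."""
    return SpecimenGeometry.default(grid_shape=(20, 20))


@pytest.fixture
def dense_geometry() -> SpecimenGeometry:
    """Default specimen with the full 1.19 mm speckle grid (strain work)."""
    return SpecimenGeometry.default()


@pytest.fixture
def quiet_noise() -> NoiseModel:
    return NoiseModel(marker_noise_um=0.0, grid_noise_um=0.0)


@pytest.fixture
def default_noise() -> NoiseModel:
    return NoiseModel()


@pytest.fixture
def loaded_spec(small_geometry) -> SpecimenSpec:
    """Trial spec with known inducible amplitudes, no migration, no strain field."""
    return SpecimenSpec(
        geometry=small_geometry,
        kinematics=GroundTruthKinematics(
            inducible_amplitude=np.array([40.0, 60.0, 20.0, 0.05, 0.05, 0.05])
        ),
        strain=None,
        noise=NoiseModel(),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240321)
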