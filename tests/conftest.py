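import numpy as np
import pytest
from hypothesis import settings

from skystereo import CameraIntrinsics, RigGeometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def intr() -> CameraIntrinsics:
    """Reference camera: 1440 px vertical, 48.8 deg FoV, 3 mm lens, 3.76 mm sensor."""
    return CameraIntrinsics()


@pytest.fixture
def rig() -> RigGeometry:
    """Reference rig: 1 m vertical baseline, axes rotated by half the FoV."""
    return RigGeometry()


@pytest.fixture
def rig_classical() -> RigGeometry:
    """Classical (perpendicular-axes) rig with the same baseline."""
    return RigGeometry(alpha=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210220)
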