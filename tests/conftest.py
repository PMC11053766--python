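import numpy as np
import pytest

from focalsim import EyeModel, make_office_scene, make_plane_scene


@pytest.fixture(scope="session")
def office_scene():
    return make_office_scene()


@pytest.fixture
def presbyope():
    """Absolute presbyope: 4 mm pupil, no residual accommodation, emmetropic."""
    return EyeModel(pupil_diameter_mm=4.0, accommodation_amplitude_D=0.0)


@pytest.fixture
def young_eye():
    return EyeModel(pupil_diameter_mm=4.0, accommodation_amplitude_D=10.0)


def two_plane_scene(seed: int, size: int = 32, near_m: float = 0.4, far_m: float = 1.0):
    """Random-noise scene split vertically between two depth planes."""
    rng = np.random.default_rng(seed)
    scene = make_plane_scene(far_m, "noise", resolution=(size, size), fov_deg=60, seed=seed)
    split = int(rng.integers(size // 4, 3 * size // 4))
    scene.depth[:, split:] = near_m
    return scene
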