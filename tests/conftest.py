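import numpy as np
import pytest
from hypothesis import settings

from prosthevis.imaging import SceneObject, generate_scene, standard_scene

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def disk_scene():
    """A single warm disk (36 C) on 20 C ambient with textured visible background."""
    return generate_scene(
        96,
        96,
        [SceneObject("disk", (48, 48), 14, 0.35, 36.0, "disk")],
        background_texture_amplitude=0.08,
        seed=3,
    )


@pytest.fixture(scope="session")
def cold_scene():
    """A single cold disk (4 C) on 20 C ambient."""
    return generate_scene(
        96,
        96,
        [SceneObject("disk", (48, 48), 14, -0.2, 4.0, "cold")],
        background_texture_amplitude=0.08,
        seed=3,
    )


@pytest.fixture(scope="session")
def person_scene():
    """The packaged reference scene: warm person, cold glass, neutral box."""
    return standard_scene(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
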