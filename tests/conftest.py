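import numpy as np
import pytest

from icemap import align_pair, default_profile
from icemap.synthetic import (
    SyntheticScene,
    make_lattice,
    make_thickness_field,
    simulate_pair,
)


@pytest.fixture(scope="session")
def profile_200_msa():
    return default_profile(200, "M_SA", "FILTER")


@pytest.fixture(scope="session")
def uniform_scene():
    """Noiseless uniform 30 nm scene at survey-magnification geometry."""
    shape = (1024, 1024)
    lattice = make_lattice(shape)
    scene = SyntheticScene(
        lattice=lattice,
        image_shape=shape,
        thickness_field=make_thickness_field("uniform", {"value": 30.0}, shape),
        poisson_noise=False,
        seed=0,
    )
    pair, truth = simulate_pair(scene)
    return scene, pair, truth


@pytest.fixture(scope="session")
def uniform_aligned(uniform_scene):
    _, pair, _ = uniform_scene
    return align_pair(pair, (0.0, 0.0))


@pytest.fixture(scope="session")
def noisy_scene():
    """Poisson-noise uniform scene at the calibrated count rate."""
    shape = (1024, 1024)
    lattice = make_lattice(shape)
    scene = SyntheticScene(
        lattice=lattice,
        image_shape=shape,
        thickness_field=make_thickness_field("uniform", {"value": 30.0}, shape),
        poisson_noise=True,
        seed=42,
    )
    pair, truth = simulate_pair(scene)
    return scene, pair, truth
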