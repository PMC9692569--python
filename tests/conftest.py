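"""Shared fixtures: geometry, camera rig, short rendered sequences."""

import numpy as np
import pytest

from flypose import (KinematicsParams, default_geometry,
                     tilted_orthogonal_cameras)
from flypose.synth import clean_backgrounds, generate_kinematics, render_sequence


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def cameras():
    return tilted_orthogonal_cameras(image_size=192)


@pytest.fixture(scope="session")
def kin_params():
    return KinematicsParams(yaw0=0.0, rng_seed=7)


@pytest.fixture(scope="session")
def short_truth(kin_params):
    """Twelve frames of the default wingbeat kinematics."""
    return generate_kinematics(kin_params, 12)


@pytest.fixture(scope="session")
def short_render(short_truth, geometry, cameras):
    """Noiseless multi-view render of the short sequence + truth masks."""
    stacks, truths = render_sequence(short_truth, geometry, cameras,
                                     noise_sigma=0.0, seed=7)
    return stacks, truths


@pytest.fixture(scope="session")
def backgrounds(cameras):
    return clean_backgrounds(cameras)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
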