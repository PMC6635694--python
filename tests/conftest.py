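"""Shared fixtures.

Synthetic bones are expensive to generate (a signed-distance field on a
quarter-millimetre grid plus marching cubes), so the common ones are
session-scoped and shared across test modules; tests must not mutate
them in place.
"""

import numpy as np
import pytest

from boneframe import frame as bframe
from boneframe import mesh as bmesh
from boneframe import synthetic as bsynth


@pytest.fixture(scope="session")
def default_bone():
    """Default synthetic metatarsal (grooves r=4 mm, skews 0/0) + truth."""
    return bsynth.make_bone()


@pytest.fixture(scope="session")
def skewed_bone():
    """Metatarsal with groove skews 0 (medial) and 3 deg (lateral)."""
    params = bsynth.BoneParams(groove_skew_medial=0.0, groove_skew_lateral=3.0)
    return params, *bsynth.make_bone(params)


@pytest.fixture(scope="session")
def default_subject():
    """Three-bone synthetic subject (metatarsal, proximal, distal)."""
    return bsynth.make_subject(seed=3)


@pytest.fixture(scope="session")
def body_frame_bone(default_bone):
    """Default bone moved into its inertial body frame."""
    mesh, _ = default_bone
    return bframe.to_body_frame(mesh)


@pytest.fixture()
def box_10_4_2():
    return bmesh.box((10.0, 4.0, 2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
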