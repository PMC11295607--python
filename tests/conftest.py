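import numpy as np
import pytest
import trimesh

import htonav as hn


@pytest.fixture(scope="session")
def tibia():
    """A mid-size synthetic tibia used across registration tests."""
    return hn.make_synthetic_tibia(hn.PatientShapeParams(seed=42))


@pytest.fixture(scope="session")
def tibia_planes(tibia):
    return hn.make_cutting_planes(tibia)


@pytest.fixture(scope="session")
def subdivided_cube():
    """A 2 mm cube with subdivided faces: corners are the only high-curvature vertices."""
    box = trimesh.creation.box(extents=(2, 2, 2)).subdivide().subdivide()
    return hn.TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces))


@pytest.fixture(scope="session")
def coarse_sphere():
    """An icosphere of radius 10 mm with 42 vertices (uniform-ish curvature)."""
    ico = trimesh.creation.icosphere(subdivisions=1, radius=10.0)
    return hn.TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


def random_transform(rng, max_angle_deg=180.0, max_t=50.0) -> hn.RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return hn.RigidTransform.from_axis_angle(
        axis, rng.uniform(0, max_angle_deg), rng.uniform(-max_t, max_t, 3)
    )
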