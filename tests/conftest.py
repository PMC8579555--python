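import numpy as np
import pytest
import trimesh as _trimesh

from atriometry import PhantomSpec, TriMesh, make_phantom


@pytest.fixture(scope="session")
def unit_cube():
    box = _trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriMesh(np.asarray(box.vertices, float), np.asarray(box.faces))


@pytest.fixture(scope="session")
def sphere_r10():
    """Icosphere, radius 10 mm, 4 subdivisions (5120 faces)."""
    return make_phantom(PhantomSpec(semiaxes=(10, 10, 10), subdivisions=4))


@pytest.fixture(scope="session")
def spheroid_20_10_10():
    """Prolate spheroid phantom, semiaxes (20, 10, 10) mm, fine mesh."""
    return make_phantom(PhantomSpec(semiaxes=(20, 10, 10), subdivisions=5))


@pytest.fixture(scope="session")
def ellipsoid_20_15_10():
    return make_phantom(PhantomSpec(semiaxes=(20, 15, 10), subdivisions=4))


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix from a seeded generator."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
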