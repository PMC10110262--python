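import numpy as np
import pytest

from bwave.mesh import TriMesh, face_geometry
from bwave.synth import make_mesh


@pytest.fixture(scope="session")
def unit_square_mesh():
    """Unit square split into two triangles."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
    faces = np.array([[0, 1, 3], [0, 3, 2]])
    return TriMesh(verts, faces, name="unit_square")


@pytest.fixture(scope="session")
def folded_strip_mesh():
    """Two flat squares joined at a 90-degree bend along x=10."""
    verts = np.array([[0, 0, 0], [0, 10, 0], [10, 0, 0], [10, 10, 0],
                      [10, 0, 10], [10, 10, 10]], float)
    faces = np.array([[0, 2, 1], [1, 2, 3], [2, 4, 3], [3, 4, 5]])
    return TriMesh(verts, faces, name="folded_strip")


@pytest.fixture(scope="session")
def small_square_mesh():
    return make_mesh("square", "N", seed=0, area_cm2=12.0)


@pytest.fixture(scope="session")
def small_cortical_mesh():
    return make_mesh("cortical_like", "N", seed=0, area_cm2=12.0)


@pytest.fixture(scope="session")
def small_cortical_locations(small_cortical_mesh):
    return face_geometry(small_cortical_mesh)
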