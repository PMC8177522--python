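import numpy as np
import pytest

import meegfem as mf
from meegfem.mesh import Mesh, VolumeConductor


@pytest.fixture(scope="session")
def unit_tet_vc():
    mesh = Mesh(
        "tetrahedron",
        np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
        np.array([[0, 1, 2, 3]]),
        np.array([0]),
    )
    mf.build_face_neighbors(mesh)
    return VolumeConductor(mesh, np.eye(3)[None])


@pytest.fixture(scope="session")
def hex_row_mesh():
    """Two unit cubes side by side along x."""
    verts = []
    for x in (0.0, 1.0, 2.0):
        for z in (0.0, 1.0):
            for y in (0.0, 1.0):
                verts.append([x, y, z])
    verts = np.array(verts)  # x-major: index = 4*ix + 2*iz + iy

    def vid(ix, iy, iz):
        return 4 * ix + 2 * iz + iy

    els = []
    for ix in range(2):
        els.append([
            vid(ix, 0, 0), vid(ix + 1, 0, 0), vid(ix + 1, 1, 0), vid(ix, 1, 0),
            vid(ix, 0, 1), vid(ix + 1, 0, 1), vid(ix + 1, 1, 1), vid(ix, 1, 1),
        ])
    mesh = Mesh("hexahedron", verts, np.array(els), np.zeros(2, int))
    mf.build_face_neighbors(mesh)
    return mesh


@pytest.fixture(scope="session")
def coarse_three_shell():
    """Three-shell sphere voxelized at 12 mm (small, fast)."""
    vc = mf.hex_sphere_model(voxel_size=0.012)
    mf.build_face_neighbors(vc.mesh)
    return vc


@pytest.fixture(scope="session")
def homog_sphere_8mm():
    vc = mf.hex_sphere_model(radii=(0.092,), conductivities=(0.33,),
                             voxel_size=0.008)
    mf.build_face_neighbors(vc.mesh)
    return vc


@pytest.fixture(scope="session")
def homog_tet_8mm(homog_sphere_8mm):
    vc = mf.hex_to_tet(homog_sphere_8mm)
    mf.build_face_neighbors(vc.mesh)
    return vc


@pytest.fixture(scope="session")
def electrodes32():
    return mf.electrode_cap(32, 0.092)


@pytest.fixture(scope="session")
def homog_assembly(homog_sphere_8mm):
    return mf.Assembly(homog_sphere_8mm, scheme="cg")


@pytest.fixture(scope="session")
def tet_assembly(homog_tet_8mm):
    return mf.Assembly(homog_tet_8mm, scheme="cg")
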