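import numpy as np
import pytest

import meegfem as mf
from meegfem.mesh import (
    Mesh,
    VolumeConductor,
    element_geometry,
    local_coordinates,
    tet_gradients,
)


def test_unit_tet_geometry(unit_tet_vc):
    geo = element_geometry(unit_tet_vc.mesh, 0)
    assert geo["volume"] == pytest.approx(1.0 / 6.0, abs=1e-15)
    assert np.allclose(geo["center"], [0.25, 0.25, 0.25])
    # outer normals are unit length and point away from the center
    for fc, n in zip(geo["face_centers"], geo["face_normals"]):
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)
        assert np.dot(n, fc - geo["center"]) > 0


def test_unit_cube_geometry(hex_row_mesh):
    geo = element_geometry(hex_row_mesh, 0)
    assert geo["volume"] == pytest.approx(1.0, abs=1e-13)
    assert np.allclose(geo["center"], [0.5, 0.5, 0.5])


def test_tet_barycentric_and_containment(unit_tet_vc):
    mesh = unit_tet_vc.mesh
    lam, inside = local_coordinates(mesh, 0, [0.25, 0.25, 0.25])
    assert inside
    assert np.allclose(lam, 0.25)
    # a vertex is tolerance-inclusive
    _, inside = local_coordinates(mesh, 0, [1.0, 0.0, 0.0])
    assert inside
    _, inside = local_coordinates(mesh, 0, [10.0, 10.0, 10.0])
    assert not inside


def test_hex_trilinear_inverse(hex_row_mesh):
    xi, inside = local_coordinates(hex_row_mesh, 1, [1.5, 0.5, 0.25])
    assert inside
    assert np.allclose(xi, [0.5, 0.5, 0.25], atol=1e-12)


def test_tet_gradients_partition_of_unity():
    rng = np.random.default_rng(3)
    verts = rng.normal(size=(20, 4, 3))
    grads, vol = tet_gradients(verts)
    assert np.abs(grads.sum(axis=1)).max() < 1e-12
    # barycentric interpolation property at the vertices
    for k in range(20):
        for i in range(4):
            lam_i = grads[k, 1:] @ (verts[k, i] - verts[k, 0])
            expect = np.zeros(3)
            if i > 0:
                expect[i - 1] = 1.0
            assert np.allclose(lam_i, expect, atol=1e-10)


def test_face_neighbors_single_tet(unit_tet_vc):
    assert (unit_tet_vc.mesh.face_neighbors == -1).all()


def test_face_neighbors_two_tets():
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], float
    )
    els = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    mesh = Mesh("tetrahedron", verts, els, np.zeros(2, int))
    mf.build_face_neighbors(mesh)
    assert (mesh.face_neighbors[0] == 1).sum() == 1
    assert (mesh.face_neighbors[1] == 0).sum() == 1


def test_face_neighbors_hex_row(hex_row_mesh):
    # element 0's +x face neighbors element 1 and vice versa
    assert (hex_row_mesh.face_neighbors[0] == 1).sum() == 1
    assert (hex_row_mesh.face_neighbors[1] == 0).sum() == 1
    assert (hex_row_mesh.face_neighbors == -1).sum() == 10


def test_nonconforming_mesh_rejected():
    verts = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1], [-1, -1, 1]],
        float,
    )
    els = np.array([[0, 1, 2, 3], [1, 2, 3, 4], [1, 2, 3, 5]])
    mesh = Mesh("tetrahedron", verts, els, np.zeros(3, int))
    with pytest.raises(ValueError, match="non-conforming"):
        mf.build_face_neighbors(mesh)


def test_interior_normals_antiparallel(coarse_three_shell):
    mesh = coarse_three_shell.mesh
    checked = 0
    for e in range(0, mesh.n_elements, 97):
        geo = element_geometry(mesh, e)
        for f in range(mesh.faces_per_element):
            nb = mesh.face_neighbors[e, f]
            if nb < 0:
                continue
            geo_nb = element_geometry(mesh, int(nb))
            fb = int(np.where(mesh.face_neighbors[nb] == e)[0][0])
            assert np.allclose(
                geo["face_normals"][f], -geo_nb["face_normals"][fb], atol=1e-12
            )
            checked += 1
    assert checked > 10


def test_volume_conductor_validation(unit_tet_vc):
    mesh = unit_tet_vc.mesh
    with pytest.raises(ValueError, match="symmetric"):
        t = np.eye(3)[None].copy()
        t[0, 0, 1] = 0.5
        VolumeConductor(mesh, t)
    with pytest.raises(ValueError, match="positive definite"):
        VolumeConductor(mesh, -np.eye(3)[None])


def test_dipole_requires_moment():
    with pytest.raises(ValueError, match="moment"):
        mf.Dipole([0, 0, 0], [0, 0, 0])


def test_fixture_sphere_volume_identity(coarse_three_shell):
    """Summed element volumes equal voxel count x voxel volume exactly."""
    vols = coarse_three_shell.mesh.element_volumes()
    expect = coarse_three_shell.mesh.n_elements * 0.012**3
    assert vols.sum() == pytest.approx(expect, rel=1e-12)
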