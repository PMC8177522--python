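import warnings

import numpy as np
import pytest

import meegfem as mf
from meegfem.mesh import Dipole
from meegfem.sources import (
    grad_u_infinity,
    partial_integration_rhs,
    represented_moment,
    subtraction_postprocess,
    subtraction_rhs,
    u_infinity,
    venant_rhs,
    whitney_rhs,
)


class TestPartialIntegration:
    def test_unit_tet_example(self, unit_tet_vc):
        b = partial_integration_rhs(
            unit_tet_vc, Dipole([0.25, 0.25, 0.25], [1, 0, 0])
        )
        assert b.storage == "sparse"
        assert np.allclose(b.to_dense(), [-1, 1, 0, 0], atol=1e-14)

    def test_sum_zero_and_linearity(self, homog_sphere_8mm):
        dip = Dipole([0.01, 0.02, 0.01], [1e-9, -2e-9, 0.5e-9])
        b1 = partial_integration_rhs(homog_sphere_8mm, dip)
        assert abs(b1.values.sum()) <= 1e-10 * np.abs(b1.values).sum()
        dip2 = Dipole(dip.position, 2 * dip.moment)
        b2 = partial_integration_rhs(homog_sphere_8mm, dip2)
        assert np.allclose(b2.values, 2 * b1.values, rtol=1e-13)

    def test_outside_mesh_rejected(self, homog_sphere_8mm):
        with pytest.raises(ValueError, match="outside"):
            partial_integration_rhs(
                homog_sphere_8mm, Dipole([1.0, 0, 0], [1e-9, 0, 0])
            )

    def test_sparse_support_independent_of_mesh(self, homog_sphere_8mm,
                                                coarse_three_shell):
        dip = Dipole([0.01, 0.0, 0.02], [0, 1e-9, 0])
        nnzs = {
            partial_integration_rhs(vc, dip).nnz
            for vc in (homog_sphere_8mm, coarse_three_shell)
        }
        assert nnzs == {8}


class TestVenant:
    def test_moment_constraints(self, homog_sphere_8mm):
        rng = np.random.default_rng(4)
        for _ in range(5):
            pos = rng.uniform(-0.03, 0.03, 3)
            mom = rng.normal(size=3) * 1e-9
            dip = Dipole(pos, mom)
            b = venant_rhs(homog_sphere_8mm, dip)
            assert abs(b.values.sum()) < 1e-10 * np.abs(b.values).max()
            m1 = b.values @ (homog_sphere_8mm.mesh.vertices[b.indices] - pos)
            assert np.linalg.norm(m1 - mom) < 1e-8 * np.linalg.norm(mom)

    def test_support_is_vertex_star(self, homog_sphere_8mm):
        dip = Dipole([0.011, 0.013, 0.009], [1e-9, 0, 0])
        b = venant_rhs(homog_sphere_8mm, dip)
        mesh = homog_sphere_8mm.mesh
        # all loaded vertices share an element with the closest vertex
        d = np.linalg.norm(mesh.vertices - dip.position, axis=1)
        vstar = int(np.argmin(d))
        star_elems = np.nonzero((mesh.elements == vstar).any(axis=1))[0]
        star_verts = set(np.unique(mesh.elements[star_elems]).tolist())
        assert set(b.indices.tolist()) <= star_verts


class TestUInfinity:
    def test_closed_form_value(self):
        v = u_infinity(Dipole([0, 0, 0], [0, 0, 1]), 1.0, [[0, 0, 2]])
        assert v[0] == pytest.approx(1.0 / (16 * np.pi), rel=1e-14)

    def test_antisymmetry_and_decay(self):
        dip = Dipole([0, 0, 0], [0, 0, 1e-9])
        pts = np.array([[0.01, 0.02, 0.03]])
        assert u_infinity(dip, 0.33, -pts)[0] == pytest.approx(
            -u_infinity(dip, 0.33, pts)[0]
        )
        # 1/r^2 decay of the dipole potential
        far = u_infinity(dip, 0.33, 100 * pts)
        assert far[0] == pytest.approx(
            u_infinity(dip, 0.33, pts)[0] / 100**2, rel=1e-12
        )

    def test_singularity_rejected(self):
        with pytest.raises(ValueError, match="singularity"):
            u_infinity(Dipole([0, 0, 0], [0, 0, 1]), 1.0, [[0, 0, 0]])

    def test_gradient_consistent_with_finite_differences(self):
        dip = Dipole([0.001, -0.002, 0.0], [1e-9, 2e-9, -0.5e-9])
        pts = np.array([[0.03, 0.01, -0.02]])
        g = grad_u_infinity(dip, 0.33, pts)[0]
        eps = 1e-7
        for d in range(3):
            e = np.zeros(3)
            e[d] = eps
            fd = (u_infinity(dip, 0.33, pts + e) -
                  u_infinity(dip, 0.33, pts - e))[0] / (2 * eps)
            assert g[d] == pytest.approx(fd, rel=1e-6)


class TestSubtraction:
    def test_homogeneous_conductor_boundary_term_only(self, homog_sphere_8mm):
        """With sigma = sigma_inf everywhere the volume term vanishes
        identically; the dense vector equals the pure boundary term."""
        dip = Dipole([0.0, 0.01, 0.02], [0, 0, 1e-9])
        b = subtraction_rhs(homog_sphere_8mm, dip)
        assert b.storage == "dense"
        assert b.post_process == "add-singularity-potential"
        # compatibility within quadrature tolerance
        assert abs(b.total()) <= 1e-6 * b.norm1()

    def test_heterogeneous_volume_term_active(self, coarse_three_shell):
        dip = Dipole([0.0, 0.0, 0.02], [0, 0, 1e-9])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b = subtraction_rhs(coarse_three_shell, dip)
        assert abs(b.total()) <= 1e-6 * b.norm1()

    def test_linearity(self, homog_sphere_8mm):
        dip = Dipole([0.0, 0.01, 0.02], [1e-9, 0, 1e-9])
        b1 = subtraction_rhs(homog_sphere_8mm, dip)
        b2 = subtraction_rhs(
            homog_sphere_8mm, Dipole(dip.position, 2 * dip.moment)
        )
        assert np.allclose(b2.dense_values, 2 * b1.dense_values, rtol=1e-12)

    def test_postprocess_identity_with_zero_uinf(self):
        pots = np.array([1.0, 2.0, 3.0])
        dip = Dipole([0, 0, 0], [0, 0, 1e-9])
        elec = np.array([[0, 0, 1.0], [0, 1.0, 0], [1.0, 0, 0]])
        out = subtraction_postprocess(pots, dip, 1e30, elec)
        assert np.allclose(out, pots - pots.mean(), atol=1e-12)

    def test_postprocess_adds_singularity_potential(self):
        dip = Dipole([0, 0, 0], [0, 0, 1e-9])
        elec = np.array([[0, 0, 0.09], [0, 0.09, 0], [0.09, 0, 0]])
        uinf = u_infinity(dip, 0.33, elec)
        out = subtraction_postprocess(np.zeros(3), dip, 0.33, elec)
        assert np.allclose(out, uinf - uinf.mean(), atol=1e-15)


class TestWhitney:
    def test_tet_only(self, homog_sphere_8mm):
        with pytest.raises(ValueError, match="tetrahedral"):
            whitney_rhs(homog_sphere_8mm,
                        Dipole([0.01, 0, 0], [1e-9, 0, 0]))

    def test_sum_zero_and_moment(self, homog_tet_8mm):
        rng = np.random.default_rng(9)
        for _ in range(5):
            dip = Dipole(rng.uniform(-0.03, 0.03, 3),
                         rng.normal(size=3) * 1e-9)
            b = whitney_rhs(homog_tet_8mm, dip)
            assert abs(b.values.sum()) < 1e-10 * np.abs(b.values).max()
            mom = represented_moment(homog_tet_8mm, dip)
            assert np.linalg.norm(mom - dip.moment) < 1e-8 * np.linalg.norm(
                dip.moment
            )

    def test_equals_partial_integration_for_p1(self, homog_tet_8mm):
        """With P1 test functions only the represented moment enters, so
        the in-element Whitney load equals partial integration exactly."""
        dip = Dipole([0.012, -0.02, 0.031], [1e-9, 2e-9, 0])
        bw = whitney_rhs(homog_tet_8mm, dip)
        bp = partial_integration_rhs(homog_tet_8mm, dip)
        assert np.array_equal(bw.indices, bp.indices)
        assert np.allclose(bw.values, bp.values, rtol=1e-9)


def test_source_model_interface(homog_sphere_8mm, coarse_three_shell):
    model = mf.make_source_model("venant", homog_sphere_8mm)
    dip = Dipole([0.0, 0.01, 0.02], [0, 1e-9, 0])
    e = model.bind(dip)
    assert e == model._element
    b = model.assemble_rhs(dip)
    assert b.storage == "sparse"
    with pytest.raises(ValueError, match="unknown source model"):
        mf.make_source_model("nosuch", homog_sphere_8mm)
    from meegfem.fem import DGSpace

    with pytest.raises(ValueError, match="not available for the DG"):
        mf.make_source_model("venant", coarse_three_shell,
                             space=DGSpace(coarse_three_shell.mesh))
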