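import numpy as np
import pytest

import meegfem as mf
from meegfem.fem import StiffnessSolver, demean, restriction_matrix


def test_unit_tet_stiffness_row(unit_tet_vc):
    """Hand-integrated P1 stiffness of the unit tet with sigma = I."""
    A = mf.assemble_stiffness_cg(unit_tet_vc).toarray()
    assert np.allclose(A[0], [0.5, -1 / 6, -1 / 6, -1 / 6], atol=1e-14)
    assert np.allclose(A, A.T)


@pytest.mark.parametrize("scheme", ["cg", "dg"])
def test_constants_in_kernel(coarse_three_shell, scheme):
    if scheme == "cg":
        A = mf.assemble_stiffness_cg(coarse_three_shell)
    else:
        A = mf.assemble_stiffness_dg(coarse_three_shell, eta=4.0)
    one = np.ones(A.shape[0])
    scale = np.abs(A.data).max()
    assert np.abs(A @ one).max() <= 1e-8 * scale
    assert np.abs(A - A.T).max() <= 1e-10 * scale


def test_stiffness_linear_in_sigma(coarse_three_shell):
    from meegfem.mesh import VolumeConductor

    A1 = mf.assemble_stiffness_cg(coarse_three_shell)
    scaled = VolumeConductor(coarse_three_shell.mesh,
                             3.0 * coarse_three_shell.tensors)
    A3 = mf.assemble_stiffness_cg(scaled)
    assert np.abs((3.0 * A1 - A3).data).max() <= 1e-12 * np.abs(A3.data).max()


def test_restriction_rows(homog_sphere_8mm, electrodes32):
    R = restriction_matrix(homog_sphere_8mm, electrodes32)
    sums = np.asarray(R.matrix.sum(axis=1)).ravel()
    assert np.abs(sums - 1.0).max() < 1e-12
    # at most nodes-per-element nonzeros per row
    nnz_per_row = np.diff(R.matrix.indptr)
    assert nnz_per_row.max() <= 8
    assert (R.distances >= 0).all()


def test_restriction_projection_matches_bruteforce(homog_sphere_8mm):
    """The projected electrode point is the true closest boundary point."""
    from meegfem.fem import (
        _boundary_triangles,
        _closest_point_on_triangles,
        boundary_faces,
    )

    mesh = homog_sphere_8mm.mesh
    electrodes = mf.electrode_cap(6, 0.11)
    R = restriction_matrix(homog_sphere_8mm, electrodes)
    bf = boundary_faces(mesh)
    tris, _ = _boundary_triangles(mesh, bf)
    for j, pos in enumerate(electrodes):
        # independent scan: min distance over every boundary triangle
        best = np.inf
        for t in range(len(tris)):
            _, d2 = _closest_point_on_triangles(pos, tris[t:t + 1])
            best = min(best, float(np.sqrt(d2[0])))
        assert R.distances[j] == pytest.approx(best, rel=1e-10)


def test_nearest_vertex_restriction(homog_sphere_8mm, electrodes32):
    R = restriction_matrix(homog_sphere_8mm, electrodes32,
                           method="nearest_vertex")
    nnz_per_row = np.diff(R.matrix.indptr)
    assert (nnz_per_row == 1).all()
    assert np.abs(np.asarray(R.matrix.sum(axis=1)) - 1.0).max() == 0


def test_solve_recovers_constructed_solution(homog_assembly):
    """b = A x0 for a mean-zero x0 is solved back to x0."""
    A = homog_assembly.A
    rng = np.random.default_rng(5)
    x0 = demean(rng.normal(size=A.shape[0]))
    b = A @ x0
    x = homog_assembly.solver.solve(b)
    scale = np.abs(x0).max()
    assert np.abs(x - x0).max() <= 1e-5 * scale


def test_solve_zero_rhs(homog_assembly):
    x = homog_assembly.solver.solve(np.zeros(homog_assembly.A.shape[0]))
    assert (x == 0).all()


def test_solve_gauge_invariance(homog_assembly):
    A = homog_assembly.A
    rng = np.random.default_rng(6)
    b = demean(rng.normal(size=A.shape[0]))
    x1 = homog_assembly.solver.solve(b)
    x2 = homog_assembly.solver.solve(b, x0=np.ones(A.shape[0]))
    assert np.abs(x1 - x2).max() <= 1e-6 * np.abs(x1).max()
    assert abs(x1.mean()) < 1e-12 * np.abs(x1).max()


def test_incompatible_rhs_rejected(homog_assembly):
    b = np.ones(homog_assembly.A.shape[0])
    with pytest.raises(ValueError, match="incompatible"):
        homog_assembly.solver.solve(b)


def test_solver_preconditioner_contract(coarse_three_shell):
    A = mf.assemble_stiffness_cg(coarse_three_shell)
    rng = np.random.default_rng(7)
    b = demean(rng.normal(size=A.shape[0]))
    xs = {}
    for prec in ("direct", "jacobi"):
        xs[prec] = StiffnessSolver(A, tol=1e-10, preconditioner=prec).solve(b)
    assert np.abs(xs["direct"] - xs["jacobi"]).max() <= 1e-5 * np.abs(
        xs["direct"]
    ).max()
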