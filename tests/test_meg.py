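import numpy as np
import pytest

import meegfem as mf
from meegfem.meg import (
    CoilSet,
    assemble_secondary_coupling,
    compute_meg_transfer,
    primary_field,
    solve_meg_forward,
)
from meegfem.mesh import Dipole, Mesh, VolumeConductor


def test_primary_field_si_value():
    """q = 1 A*m at the origin, coil at (1,0,0) m measuring along y:
    B = (mu0/4pi) q x r / r^3 -> exactly 1e-7 T."""
    coils = CoilSet([[1.0, 0, 0]], [[0, 1.0, 0]])
    B = primary_field(Dipole([0, 0, 0], [0, 0, 1.0]), coils)
    assert B[0] == pytest.approx(1e-7, rel=1e-15)


def test_primary_field_parallel_vanishes():
    coils = CoilSet([[0, 0, 1.0]], [[0, 1.0, 0]])
    B = primary_field(Dipole([0, 0, 0], [0, 0, 1.0]), coils)
    assert B[0] == 0.0


def test_primary_field_linear_in_moment():
    coils = mf.magnetometer_shell(8, 0.2)
    d = Dipole([0.01, 0, 0.02], [1e-9, 2e-9, 0])
    B1 = primary_field(d, coils)
    B2 = primary_field(Dipole(d.position, 3 * d.moment), coils)
    assert np.allclose(B2, 3 * B1, rtol=1e-14)


def test_coil_direction_must_be_unit():
    with pytest.raises(ValueError, match="unit"):
        CoilSet([[0, 0, 1.0]], [[0, 0, 2.0]])


def _two_hex_conductor(sigma0=1.0, sigma1=1.0):
    verts = []
    for x in (0.0, 0.01, 0.02):
        for z in (0.0, 0.01):
            for y in (0.0, 0.01):
                verts.append([x, y, z])

    def vid(ix, iy, iz):
        return 4 * ix + 2 * iz + iy

    els = []
    for ix in range(2):
        els.append([
            vid(ix, 0, 0), vid(ix + 1, 0, 0), vid(ix + 1, 1, 0), vid(ix, 1, 0),
            vid(ix, 0, 1), vid(ix + 1, 0, 1), vid(ix + 1, 1, 1), vid(ix, 1, 1),
        ])
    mesh = Mesh("hexahedron", np.array(verts), np.array(els),
                np.array([0, 1]))
    mf.build_face_neighbors(mesh)
    tensors = np.stack([sigma0 * np.eye(3), sigma1 * np.eye(3)])
    return VolumeConductor(mesh, tensors)


def test_secondary_coupling_linear_in_sigma():
    coils = CoilSet([[0.05, 0.05, 0.05]],
                    [[1 / np.sqrt(3)] * 3])
    S1 = assemble_secondary_coupling(_two_hex_conductor(1.0, 1.0), coils,
                                     min_coil_distance=0.0)
    S2 = assemble_secondary_coupling(_two_hex_conductor(2.0, 2.0), coils,
                                     min_coil_distance=0.0)
    assert np.allclose(S2, 2 * S1, rtol=1e-13)


def test_secondary_coupling_additive_per_element():
    """S is linear in sigma element by element: the full coupling is the
    sum of single-element contributions (a near-zero-sigma element
    contributes nearly nothing)."""
    coil = CoilSet([[0.05, 0.05, 0.05]], [[0, 0, 1.0]])
    eps = 1e-12
    S_full = assemble_secondary_coupling(_two_hex_conductor(1.0, 1.0), coil,
                                         min_coil_distance=0.0)
    S_e0 = assemble_secondary_coupling(_two_hex_conductor(1.0, eps), coil,
                                       min_coil_distance=0.0)
    S_e1 = assemble_secondary_coupling(_two_hex_conductor(eps, 1.0), coil,
                                       min_coil_distance=0.0)
    scale = np.abs(S_full).max()
    assert np.abs(S_full - (S_e0 + S_e1)).max() <= 1e-9 * scale
    # each single-element coupling is a strict part of the whole
    assert np.abs(S_e0).max() < scale * (1 + 1e-12)
    assert np.abs(S_full - S_e0).max() > 1e-3 * scale


def test_secondary_quadrature_converges():
    """Quadrature-refinement oracle on a 2-element mesh: the order-8 rule
    agrees with an order-12 reference to 1e-6 relative, and increasing
    the order never loses accuracy."""
    vc = _two_hex_conductor()
    coils = CoilSet([[0.05, 0.04, 0.06]], [[0, 1.0, 0]])
    S12 = assemble_secondary_coupling(vc, coils, quad_order=12,
                                      min_coil_distance=0.0)
    denom = np.abs(S12).max()
    errs = {}
    for order in (2, 4, 8):
        S = assemble_secondary_coupling(vc, coils, quad_order=order,
                                        min_coil_distance=0.0)
        errs[order] = np.abs(S - S12).max() / denom
    assert errs[8] <= 1e-6
    assert errs[8] <= errs[4] <= errs[2]
    assert errs[2] <= 1e-2  # smooth integrand: even low order is close


def test_min_coil_distance_enforced(homog_sphere_8mm):
    coils = CoilSet([[0, 0, 0.093]], [[0, 0, 1.0]])
    with pytest.raises(ValueError, match="coil"):
        assemble_secondary_coupling(homog_sphere_8mm, coils)


def test_meg_transfer_equals_direct(homog_sphere_8mm, homog_assembly):
    coils = mf.magnetometer_shell(6, 0.13)
    T = compute_meg_transfer(homog_sphere_8mm, coils, homog_assembly)
    assert T.matrix.shape == (6, homog_assembly.space.ndof)
    rng = np.random.default_rng(3)
    dips = [Dipole(rng.uniform(-0.02, 0.02, 3), rng.normal(size=3) * 1e-9)
            for _ in range(3)]
    via = solve_meg_forward(homog_sphere_8mm, dips, coils,
                            assembly=homog_assembly, transfer=T)
    direct = solve_meg_forward(homog_sphere_8mm, dips, coils,
                               assembly=homog_assembly)
    assert np.abs(via - direct).max() <= 10 * homog_assembly.tol * np.abs(
        direct
    ).max()


def test_subtraction_needs_acknowledgement(homog_sphere_8mm, homog_assembly):
    coils = mf.magnetometer_shell(4, 0.13)
    dip = Dipole([0, 0, 0.02], [1e-9, 0, 0])
    with pytest.raises(ValueError, match="singularity"):
        solve_meg_forward(homog_sphere_8mm, [dip], coils,
                          assembly=homog_assembly,
                          source_model="subtraction")


def test_meg_requires_cg(coarse_three_shell):
    asm = mf.Assembly(coarse_three_shell, scheme="dg", eta=4.0,
                      preconditioner="jacobi")
    coils = mf.magnetometer_shell(4, 0.13)
    with pytest.raises(ValueError, match="CG"):
        compute_meg_transfer(coarse_three_shell, coils, asm)


def test_meg_linearity(homog_sphere_8mm, homog_assembly):
    coils = mf.magnetometer_shell(6, 0.13)
    pos = [0.0, 0.01, 0.03]
    q1, q2 = np.array([1e-9, 0, 0]), np.array([0, 1e-9, 1e-9])
    S = assemble_secondary_coupling(homog_sphere_8mm, coils)
    B = solve_meg_forward(
        homog_sphere_8mm,
        [Dipole(pos, q1), Dipole(pos, q2), Dipole(pos, q1 + q2)],
        coils, assembly=homog_assembly, secondary_coupling=S,
    )
    assert np.abs(B[:, 0] + B[:, 1] - B[:, 2]).max() <= 1e-5 * np.abs(
        B[:, 2]
    ).max()
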