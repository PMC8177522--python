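"""MEG forward computation via the Biot-Savart law.

The magnetic field splits into the primary field of the dipole itself
(analytic) and the secondary field of the volume return currents
j^s = -sigma grad(u), which is integrated numerically per element:

    B^s(y).d = -(mu0/4pi) sum_K int_K <sigma grad(u_h) x (y-x)/||y-x||^3, d>

The secondary coupling matrix S collects these integrals per potential
degree of freedom, so B^s = S x; combining with the stiffness solve
gives the MEG transfer matrix T_meg = S A^-1 (row-wise symmetric
solves).  MEG is restricted to the CG discretization — the straight
sigma grad(u_h) evaluation is not adequate for DG — and to the direct
source models; the subtraction model's solution lacks the singularity
contribution and must be acknowledged explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import CGSpace, demean
from .mesh import Dipole, VolumeConductor, hex_shape, hex_shape_grad, tet_gradients
from .quadrature import hex_rule, tet_rule
from .sphere import MU0_OVER_4PI

_CHUNK = 5000


@dataclass
class CoilSet:
    """Magnetometer positions and unit measurement directions."""

    positions: np.ndarray
    directions: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.directions = np.atleast_2d(np.asarray(self.directions, float))
        if self.positions.shape != self.directions.shape:
            raise ValueError("positions/directions shape mismatch")
        norms = np.linalg.norm(self.directions, axis=1)
        if (np.abs(norms - 1.0) > 1e-12).any():
            raise ValueError("coil directions must be unit vectors")

    def __len__(self):
        return len(self.positions)


def primary_field(dipole: Dipole, coils: CoilSet) -> np.ndarray:
    """Projected primary field B^p(y).d = (mu0/4pi) (q x R)/||R||^3 . d."""
    R = coils.positions - dipole.position
    r = np.linalg.norm(R, axis=1)
    if (r == 0).any():
        raise ValueError("coil coincides with the dipole position")
    Bp = MU0_OVER_4PI * np.cross(dipole.moment[None, :], R) / r[:, None] ** 3
    return np.einsum("jd,jd->j", Bp, coils.directions)


def _element_quadrature_data(vc: VolumeConductor, sl: slice, order: int):
    """Points (m,Q,3), sigma-weighted basis gradients (m,Q,nb,3) and
    weights incl. |J| (m,Q) for secondary-field integration."""
    mesh = vc.mesh
    verts = mesh.element_vertices(sl)
    if mesh.element_kind == "tetrahedron":
        ref, w = tet_rule(order)
        grads, vol = tet_gradients(verts)  # (m,4,3)
        e = verts[:, 1:] - verts[:, :1]
        pts = verts[:, None, 0] + np.einsum("qe,med->mqd", ref, e)
        W = 6.0 * vol[:, None] * w[None, :]
        sg = np.einsum("mab,mnb->mna", vc.tensors[sl], grads)
        sg = np.broadcast_to(sg[:, None], (len(verts), len(w), 4, 3))
        return pts, sg, W
    ref, w = hex_rule(order)
    phi = hex_shape(ref)
    dphi = hex_shape_grad(ref)
    pts = np.einsum("qn,mnd->mqd", phi, verts)
    J = np.einsum("mnd,qne->mqde", verts, dphi)
    det = np.abs(np.linalg.det(J))
    g = np.einsum("qne,mqed->mqnd", dphi, np.linalg.inv(J))
    sg = np.einsum("mab,mqnb->mqna", vc.tensors[sl], g)
    return pts, sg, det * w[None, :]


def min_coil_distance_default(vc: VolumeConductor) -> float:
    """Two element diameters: keeps the 1/r^2 kernel resolvable by the
    fixed-order quadrature."""
    return 2.0 * float(vc.mesh.element_diameters().max())


def assemble_secondary_coupling(vc: VolumeConductor, coils: CoilSet,
                                quad_order: int = 4,
                                min_coil_distance: float | None = None
                                ) -> np.ndarray:
    """Dense p_c x n matrix mapping CG potential coefficients to the
    projected secondary field at the coils."""
    mesh = vc.mesh
    space = CGSpace(mesh)
    if min_coil_distance is None:
        min_coil_distance = min_coil_distance_default(vc)
    S = np.zeros((len(coils), space.ndof))
    centers = mesh.element_centers()
    diam = mesh.element_diameters().max()
    for y in coils.positions:
        d = np.linalg.norm(centers - y, axis=1).min()
        if d + 0.5 * diam < min_coil_distance:
            raise ValueError(
                "coil closer to the mesh than the minimum coil distance "
                f"({d:.4g} < {min_coil_distance:.4g})"
            )
    for start in range(0, mesh.n_elements, _CHUNK):
        sl = slice(start, min(start + _CHUNK, mesh.n_elements))
        pts, sg, W = _element_quadrature_data(vc, sl, quad_order)
        conn = mesh.elements[sl]
        for j in range(len(coils)):
            R = coils.positions[j] - pts  # (m,Q,3)
            r3 = np.linalg.norm(R, axis=2) ** 3
            w_vec = R / r3[..., None]
            # <sg x w, d> = sg . (w x d)
            v = np.cross(w_vec, coils.directions[j])
            contrib = -MU0_OVER_4PI * np.einsum(
                "mqnd,mqd,mq->mn", sg, v, W
            )
            np.add.at(S[j], conn, contrib)
    return S


@dataclass
class MEGTransfer:
    """p_c x n map from right-hand sides to projected secondary fields."""

    matrix: np.ndarray
    provenance: dict


def compute_meg_transfer(vc: VolumeConductor, coils: CoilSet, assembly,
                         quad_order: int = 4) -> MEGTransfer:
    """T_meg = S A^-1 via one symmetric solve per coil."""
    if assembly.scheme != "cg":
        raise ValueError("MEG is only supported for the CG discretization")
    S = assemble_secondary_coupling(vc, coils, quad_order=quad_order)
    T = np.empty_like(S)
    for j in range(len(coils)):
        T[j] = assembly.solver.solve(demean(S[j]), check_compatibility=False)
    from .eeg import _conductor_signature, _sensor_hash

    prov = {
        "kind": "meg",
        "scheme": "cg",
        "n": int(S.shape[1]),
        "p": int(len(coils)),
        "tolerance": assembly.tol,
        "sensors": _sensor_hash(coils.positions),
        "conductor": _conductor_signature(vc),
    }
    return MEGTransfer(T, prov)


def solve_meg_forward(vc: VolumeConductor, dipoles, coils: CoilSet,
                      assembly=None, source_model: str = "partial_integration",
                      quad_order: int = 4, transfer: MEGTransfer | None = None,
                      secondary_coupling: np.ndarray | None = None,
                      acknowledge_incomplete_subtraction: bool = False,
                      **model_params) -> np.ndarray:
    """Projected total field B.d (primary + secondary) per coil and dipole.

    ``source_model`` must be one of the direct models unless
    ``acknowledge_incomplete_subtraction`` is set: the subtraction
    solution omits the singularity potential's field contribution.
    """
    from .eeg import Assembly

    if source_model == "subtraction" and not acknowledge_incomplete_subtraction:
        raise ValueError(
            "MEG with the subtraction model omits the singularity "
            "contribution; pass acknowledge_incomplete_subtraction=True to "
            "proceed"
        )
    if assembly is None:
        assembly = Assembly(vc, scheme="cg")
    if assembly.scheme != "cg":
        raise ValueError("MEG is only supported for the CG discretization")
    model = assembly.source_model(source_model, **model_params)
    if transfer is None and secondary_coupling is None:
        secondary_coupling = assemble_secondary_coupling(
            vc, coils, quad_order=quad_order
        )
    out = np.empty((len(coils), len(dipoles)))
    for k, dip in enumerate(dipoles):
        model.bind(dip)
        b = model.assemble_rhs(dip)
        if transfer is not None:
            if rhs_n := transfer.provenance.get("n"):
                if rhs_n != b.n:
                    raise ValueError("transfer does not match the FEM space")
            Bs = (
                transfer.matrix[:, b.indices] @ b.values
                if b.storage == "sparse"
                else transfer.matrix @ demean(b.to_dense())
            )
        else:
            x = assembly.solver.solve(demean(b.to_dense()),
                                      check_compatibility=False)
            Bs = secondary_coupling @ x
        out[:, k] = primary_field(dip, coils) + Bs
    return out
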