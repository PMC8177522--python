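"""Continuous-Galerkin stiffness assembly, electrode restriction, and the
gauge-fixed linear solve.

The discrete operator is the pure-Neumann stiffness matrix
``A_ij = sum_K int_K <sigma grad phi_i, grad phi_j>`` with P1 elements on
tetrahedra (assembled exactly from the constant barycentric gradients)
and Q1 elements on hexahedra (2x2x2 Gauss quadrature).  A is symmetric
positive semidefinite with the constants as its one-dimensional kernel;
the gauge is fixed by demeaning right-hand sides and solutions rather
than grounding a node, which preserves the symmetry the transfer-matrix
transpose trick relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import (
    NONE_NEIGHBOR,
    Mesh,
    VolumeConductor,
    hex_shape_grad,
    local_coordinates,
    shape_values,
    tet_gradients,
)
from .quadrature import hex_rule

_CHUNK = 20000


class CGSpace:
    """Vertex-based P1/Q1 space: one degree of freedom per mesh vertex."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.ndof = mesh.n_vertices

    def element_dofs(self, e: int) -> np.ndarray:
        return self.mesh.elements[e]

    def point_evaluation(self, e: int, local) -> tuple[np.ndarray, np.ndarray]:
        """(global dof indices, shape values) at local coords in element e."""
        return self.mesh.elements[e], shape_values(self.mesh, local)


class DGSpace:
    """Elementwise P1/Q1 space: ``nodes_per_element`` dofs per element."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.nb = mesh.nodes_per_element
        self.ndof = mesh.n_elements * self.nb

    def element_dofs(self, e: int) -> np.ndarray:
        return np.arange(e * self.nb, (e + 1) * self.nb)

    def point_evaluation(self, e: int, local) -> tuple[np.ndarray, np.ndarray]:
        return self.element_dofs(e), shape_values(self.mesh, local)


def element_stiffness_matrices(vc: VolumeConductor, sl: slice,
                               quad_order: int = 2) -> np.ndarray:
    """Per-element stiffness blocks int_K <sigma grad phi_n, grad phi_k>
    for the elements in ``sl``; returns (m, nb, nb)."""
    mesh = vc.mesh
    verts = mesh.element_vertices(sl)
    if mesh.element_kind == "tetrahedron":
        grads, vol = tet_gradients(verts)  # (m,4,3), (m,)
        if (vol <= 0).any() or not np.isfinite(vol).all():
            raise ValueError("degenerate element Jacobian")
        sg = np.einsum("mab,mnb->mna", vc.tensors[sl], grads)
        return np.einsum("mna,mka->mnk", sg, grads) * vol[:, None, None]
    pts, w = hex_rule(quad_order)
    dphi = hex_shape_grad(pts)  # (Q,8,3)
    J = np.einsum("mnd,qne->mqde", verts, dphi)  # (m,Q,3,3)
    det = np.linalg.det(J)
    if (det <= 0).any():
        raise ValueError("degenerate element Jacobian")
    Jinv = np.linalg.inv(J)
    g = np.einsum("qne,mqed->mqnd", dphi, Jinv)  # global gradients
    sg = np.einsum("mab,mqnb->mqna", vc.tensors[sl], g)
    return np.einsum("mqna,mqka,mq,q->mnk", sg, g, det, w)


def assemble_stiffness_cg(vc: VolumeConductor, quad_order: int = 2) -> sp.csr_array:
    """Assemble the CG stiffness matrix of ``div(sigma grad)`` (pure Neumann)."""
    mesh = vc.mesh
    nb = mesh.nodes_per_element
    rows, cols, vals = [], [], []
    for start in range(0, mesh.n_elements, _CHUNK):
        sl = slice(start, min(start + _CHUNK, mesh.n_elements))
        ke = element_stiffness_matrices(vc, sl, quad_order)
        conn = mesh.elements[sl]
        rows.append(np.repeat(conn, nb, axis=1).ravel())
        cols.append(np.tile(conn, (1, nb)).ravel())
        vals.append(ke.ravel())
    n = mesh.n_vertices
    A = sp.coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    A.sum_duplicates()
    return A


# ---------------------------------------------------------------------------
# electrode restriction


def boundary_faces(mesh: Mesh) -> np.ndarray:
    """(k, 2) array of (element, local face) pairs on the mesh boundary."""
    if mesh.face_neighbors is None:
        raise ValueError("face neighbors not built")
    el, fa = np.nonzero(mesh.face_neighbors == NONE_NEIGHBOR)
    return np.stack([el, fa], axis=1)


def _closest_point_on_triangles(p, tri):
    """Closest points of ``p`` (3,) on triangles ``tri`` (m,3,3); returns
    (points (m,3), squared distances (m,)).  Ericson's region algorithm,
    vectorized."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("md,md->m", ab, ap)
    d2 = np.einsum("md,md->m", ac, ap)
    bp = p - b
    d3 = np.einsum("md,md->m", ab, bp)
    d4 = np.einsum("md,md->m", ac, bp)
    cp = p - c
    d5 = np.einsum("md,md->m", ab, cp)
    d6 = np.einsum("md,md->m", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4
    out = np.empty_like(tri[:, 0])
    # vertex regions
    m_a = (d1 <= 0) & (d2 <= 0)
    m_b = (d3 >= 0) & (d4 <= d3)
    m_c = (d6 >= 0) & (d5 <= d6)
    # edge regions
    v = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0)
    m_ab = (~m_a) & (~m_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    wq = d2 / np.where(d2 - d6 == 0, 1, d2 - d6)
    m_ac = (~m_a) & (~m_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    wbc = num / np.where(den == 0, 1, den)
    m_bc = (~m_b) & (~m_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    inner = ~(m_a | m_b | m_c | m_ab | m_ac | m_bc)
    denom = np.where(va + vb + vc == 0, 1, va + vb + vc)
    vv = vb / denom
    ww = vc / denom
    out[m_a] = a[m_a]
    out[m_b] = b[m_b]
    out[m_c] = c[m_c]
    out[m_ab] = a[m_ab] + v[m_ab, None] * ab[m_ab]
    out[m_ac] = a[m_ac] + wq[m_ac, None] * ac[m_ac]
    out[m_bc] = b[m_bc] + wbc[m_bc, None] * (c[m_bc] - b[m_bc])
    out[inner] = a[inner] + vv[inner, None] * ab[inner] + ww[inner, None] * ac[inner]
    d = p - out
    return out, np.einsum("md,md->m", d, d)


def _boundary_triangles(mesh: Mesh, bfaces):
    """Triangulated boundary faces: (tri vertices (m,3,3), face index (m,))."""
    tris, owner = [], []
    for i, (e, f) in enumerate(bfaces):
        loc = mesh.local_faces[f]
        pts = mesh.vertices[mesh.elements[e][list(loc)]]
        if len(loc) == 3:
            tris.append(pts)
            owner.append(i)
        else:
            tris.append(pts[[0, 1, 2]])
            tris.append(pts[[0, 2, 3]])
            owner.extend([i, i])
    return np.array(tris), np.array(owner)


@dataclass
class Restriction:
    """Sparse evaluation map from FEM coefficients to electrode potentials.

    Each row interpolates the discrete potential at the electrode's
    projection onto the nearest boundary face; rows sum to one.
    """

    matrix: sp.csr_array
    projected: np.ndarray
    distances: np.ndarray
    elements: np.ndarray = field(default=None)


def restriction_matrix(
    vc: VolumeConductor,
    electrodes,
    space: CGSpace | DGSpace | None = None,
    method: str = "projected",
) -> Restriction:
    """Build the p x n restriction matrix for electrode positions.

    ``method="projected"`` (default) projects each electrode to the
    closest point on the mesh boundary and uses the shape-function values
    of the adjacent element; ``method="nearest_vertex"`` snaps to the
    closest boundary vertex (CG only, for cross-checks).
    """
    mesh = vc.mesh
    electrodes = np.atleast_2d(np.asarray(electrodes, dtype=float))
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    if len(electrodes) < 2:
        raise ValueError("need at least 2 electrodes")
    if space is None:
        space = CGSpace(mesh)
    if mesh.face_neighbors is None:
        raise ValueError("face neighbors not built")
    bfaces = boundary_faces(mesh)
    tris, owner = _boundary_triangles(mesh, bfaces)

    if method == "nearest_vertex":
        if not isinstance(space, CGSpace):
            raise ValueError("nearest_vertex restriction requires a CG space")
        bverts = np.unique(
            np.concatenate(
                [
                    mesh.elements[e][list(mesh.local_faces[f])]
                    for e, f in bfaces
                ]
            )
        )
        rows, cols, vals, proj, dist, elems = [], [], [], [], [], []
        for j, pos in enumerate(electrodes):
            d = np.linalg.norm(mesh.vertices[bverts] - pos, axis=1)
            k = int(np.argmin(d))
            rows.append(j)
            cols.append(int(bverts[k]))
            vals.append(1.0)
            proj.append(mesh.vertices[bverts[k]])
            dist.append(d[k])
            elems.append(-1)
        R = sp.csr_array(
            (vals, (rows, cols)), shape=(len(electrodes), space.ndof)
        )
        return Restriction(R, np.array(proj), np.array(dist), np.array(elems))

    rows, cols, vals, proj, dist, elems = [], [], [], [], [], []
    for j, pos in enumerate(electrodes):
        _, d2 = _closest_point_on_triangles(pos, tris)
        t = int(np.argmin(d2))
        cp, _ = _closest_point_on_triangles(pos, tris[t:t + 1])
        e = int(bfaces[owner[t], 0])
        local, _ = local_coordinates(mesh, e, cp[0])
        dofs, phi = space.point_evaluation(e, local)
        rows.extend([j] * len(dofs))
        cols.extend(int(i) for i in dofs)
        vals.extend(float(x) for x in phi)
        proj.append(cp[0])
        dist.append(float(np.sqrt(d2[t])))
        elems.append(e)
    R = sp.csr_array((vals, (rows, cols)), shape=(len(electrodes), space.ndof))
    return Restriction(R, np.array(proj), np.array(dist), np.array(elems))


# ---------------------------------------------------------------------------
# gauge-fixed solve


def demean(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean()


class StiffnessSolver:
    """Conjugate-gradient solve of the singular Neumann system.

    The preconditioner contract accepts any symmetric positive operator.
    ``"direct"`` uses a sparse LU factorization of a grounded copy of A
    (A + alpha e0 e0^T), under which CG converges in a couple of
    iterations and repeated right-hand sides (transfer matrices) amortize
    the factorization.  ``"jacobi"`` scales by the inverse diagonal and
    is preferred for very large systems.  ``"auto"`` picks direct below
    200k unknowns.
    """

    def __init__(self, A: sp.csr_array, tol: float = 1e-8,
                 preconditioner: str = "auto", maxiter: int = 20000):
        self.A = A.tocsr()
        self.n = A.shape[0]
        self.tol = float(tol)
        self.maxiter = int(maxiter)
        if preconditioner == "auto":
            # LU fill-in on 3D stencils makes the direct preconditioner
            # worthwhile only for small systems; Jacobi-CG wins beyond that
            preconditioner = "direct" if self.n <= 20_000 else "jacobi"
        self.preconditioner = preconditioner
        self._M = None

    def _make_preconditioner(self):
        if self._M is not None:
            return self._M
        if self.preconditioner == "direct":
            diag = self.A.diagonal()
            alpha = float(diag.mean())
            Ag = self.A.tolil(copy=True)
            Ag[0, 0] = Ag[0, 0] + alpha
            lu = spla.splu(sp.csc_matrix(Ag.tocsc()))
            self._M = spla.LinearOperator(
                (self.n, self.n), matvec=lu.solve, dtype=float
            )
        elif self.preconditioner == "jacobi":
            dinv = 1.0 / self.A.diagonal()
            self._M = spla.LinearOperator(
                (self.n, self.n), matvec=lambda x: dinv * x, dtype=float
            )
        elif self.preconditioner == "none":
            self._M = None
            return None
        else:
            raise ValueError(f"unknown preconditioner {self.preconditioner!r}")
        return self._M

    def solve(self, b, x0=None, check_compatibility: bool = True) -> np.ndarray:
        """Solve A x = b to relative residual <= tol; returns demeaned x."""
        b = np.asarray(b, dtype=float)
        if b.shape != (self.n,):
            raise ValueError("right-hand side has wrong length")
        nb1 = np.abs(b).sum()
        if nb1 == 0:
            return np.zeros(self.n)
        if check_compatibility and abs(b.sum()) > 1e-6 * nb1:
            raise ValueError(
                "incompatible right-hand side for the pure-Neumann problem "
                f"(|sum b| = {abs(b.sum()):.3e} > 1e-6 * ||b||_1)"
            )
        b = demean(b)
        M = self._make_preconditioner()
        if x0 is not None:
            x0 = demean(np.asarray(x0, dtype=float))
        nb = np.linalg.norm(b)
        x, info = spla.cg(
            self.A, b, x0=x0, rtol=self.tol * 0.5, atol=0.0,
            maxiter=self.maxiter, M=M,
        )
        x = demean(x)
        res = np.linalg.norm(self.A @ x - b) / nb
        if res > self.tol:
            raise RuntimeError(
                f"CG did not converge: relative residual {res:.3e} "
                f"(info={info})"
            )
        return x


def solve(A, b, tol: float = 1e-8, preconditioner: str = "auto",
          x0=None) -> np.ndarray:
    """One-shot gauge-fixed solve; see :class:`StiffnessSolver`."""
    return StiffnessSolver(A, tol=tol, preconditioner=preconditioner).solve(
        b, x0=x0
    )
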