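"""Right-hand-side assembly for the dipole source models.

All models discretize the source term q . grad(delta_xdp) of the Poisson
dipole problem under the sign convention fixed by the weak form

    int <sigma grad u, grad phi_i> = int j^p . grad phi_i  =: b_i,

so a dipole pointing at an electrode raises its potential (tested
against the analytic sphere solution).

Direct models (partial integration, St. Venant, Whitney) produce sparse
right-hand sides whose support is bounded independently of the mesh
size; the subtraction model splits u = u_inf + u_corr around a locally
homogeneous conductivity sigma_inf and produces a dense right-hand side
for the correction potential plus a post-processing step that adds the
singularity potential back at the sensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fem import CGSpace, DGSpace, boundary_faces, demean
from .locate import build_center_index, locate
from .mesh import (
    Dipole,
    Mesh,
    VolumeConductor,
    hex_shape,
    hex_shape_grad,
    local_coordinates,
    tet_gradients,
)
from .quadrature import hex_rule, quad_face_rule, tet_rule, triangle_rule

_CHUNK = 20000


@dataclass
class RightHandSide:
    """Source-term vector with sparse or dense storage.

    ``post_process`` is ``"none"`` for direct models and
    ``"add-singularity-potential"`` for the subtraction model.
    """

    n: int
    storage: str  # "sparse" | "dense"
    indices: np.ndarray | None = None
    values: np.ndarray | None = None
    dense_values: np.ndarray | None = None
    post_process: str = "none"

    def to_dense(self) -> np.ndarray:
        if self.storage == "dense":
            return self.dense_values
        out = np.zeros(self.n)
        np.add.at(out, self.indices, self.values)
        return out

    def total(self) -> float:
        if self.storage == "dense":
            return float(self.dense_values.sum())
        return float(self.values.sum())

    def norm1(self) -> float:
        return float(np.abs(self.to_dense()).sum())

    @property
    def nnz(self) -> int:
        if self.storage == "dense":
            return int(np.count_nonzero(self.dense_values))
        return len(self.indices)


def _containing_element(vc: VolumeConductor, dipole: Dipole, element=None,
                        locator=None):
    if element is not None:
        return int(element)
    mesh = vc.mesh
    if mesh.face_neighbors is None:
        from .locate import linear_locate

        e = linear_locate(mesh, dipole.position)
    else:
        if locator is None:
            locator = build_center_index(mesh)
        e = locate(mesh, locator, dipole.position)
    if e is None:
        raise ValueError("dipole position lies outside the mesh")
    return e


def _basis_gradients_at(mesh: Mesh, e: int, local) -> np.ndarray:
    """Global shape-function gradients at local coords in element e: (nb,3)."""
    verts = mesh.vertices[mesh.elements[e]]
    if mesh.element_kind == "tetrahedron":
        g, _ = tet_gradients(verts[None])
        return g[0]
    dphi = hex_shape_grad(np.asarray(local, dtype=float))
    J = np.einsum("nd,ne->de", verts, dphi)
    return dphi @ np.linalg.inv(J)


def partial_integration_rhs(vc: VolumeConductor, dipole: Dipole,
                            space=None, element=None, locator=None
                            ) -> RightHandSide:
    """Partial-integration source model: b_i = q . grad phi_i(x_dp) on the
    basis functions of the containing element (sparse)."""
    mesh = vc.mesh
    if space is None:
        space = CGSpace(mesh)
    e = _containing_element(vc, dipole, element, locator)
    local, inside = local_coordinates(mesh, e, dipole.position)
    if not inside:
        raise ValueError("dipole position not inside the located element")
    grads = _basis_gradients_at(mesh, e, local)
    vals = grads @ dipole.moment
    dofs = space.element_dofs(e)
    return RightHandSide(space.ndof, "sparse", np.asarray(dofs), vals)


# ---------------------------------------------------------------------------
# St. Venant


def _vertex_star(mesh: Mesh, vertex: int):
    """Elements touching ``vertex`` and the unique vertices of those elements."""
    elems = np.nonzero((mesh.elements == vertex).any(axis=1))[0]
    verts = np.unique(mesh.elements[elems])
    return elems, verts


def venant_rhs(vc: VolumeConductor, dipole: Dipole, reference_length=None,
               moment_order: int = 2, regularization: float = 1e-6,
               element=None, locator=None) -> RightHandSide:
    """St. Venant source model: monopole loads on the vertex star of the
    mesh vertex closest to the dipole.

    The loads reproduce the dipole's zeroth moment (zero) and first
    moment (q) exactly via equality constraints; higher moments up to
    ``moment_order`` and a Tikhonov term ``regularization * ||a||^2`` are
    minimized in scaled coordinates (x_v - x_dp)/reference_length.  The
    default reference length is the mean edge length of the star.
    """
    mesh = vc.mesh
    e = _containing_element(vc, dipole, element, locator)
    conn = mesh.elements[e]
    dv = np.linalg.norm(mesh.vertices[conn] - dipole.position, axis=1)
    v_star = int(conn[np.argmin(dv)])
    star_elems, star_verts = _vertex_star(mesh, v_star)
    k = len(star_verts)
    if k < 4:
        raise ValueError("vertex star too small for moment matching")
    if reference_length is None:
        ev = mesh.element_vertices(star_elems)
        d = np.linalg.norm(ev[:, :, None, :] - ev[:, None, :, :], axis=-1)
        reference_length = float(d[d > 0].mean())
    d = (mesh.vertices[star_verts] - dipole.position) / reference_length  # (k,3)

    # exact constraints: zeroth moment 0, first moment q (scaled)
    C = np.vstack([np.ones((1, k)), d.T])  # (4,k)
    t = np.concatenate([[0.0], dipole.moment / reference_length])
    # penalized objective: higher moments + Tikhonov
    S_rows = []
    if moment_order >= 2:
        for a in range(3):
            for b in range(a, 3):
                S_rows.append(d[:, a] * d[:, b])
    S = np.array(S_rows) if S_rows else np.zeros((0, k))
    H = 2.0 * (S.T @ S + regularization * np.eye(k))
    kkt = np.block([[H, C.T], [C, np.zeros((4, 4))]])
    rhs = np.concatenate([np.zeros(k), t])
    sol = np.linalg.solve(kkt, rhs)
    loads = sol[:k]
    return RightHandSide(mesh.n_vertices, "sparse", star_verts.copy(), loads)


# ---------------------------------------------------------------------------
# subtraction


def u_infinity(dipole: Dipole, sigma_inf: float, points) -> np.ndarray:
    """Dipole potential in an unbounded homogeneous medium:
    u_inf(y) = q.(y - x_dp) / (4 pi sigma_inf ||y - x_dp||^3)."""
    if sigma_inf <= 0:
        raise ValueError("sigma_inf must be positive")
    R = np.atleast_2d(np.asarray(points, dtype=float)) - dipole.position
    r = np.linalg.norm(R, axis=1)
    if (r == 0).any():
        raise ValueError("evaluation at the dipole singularity")
    return (R @ dipole.moment) / (4.0 * np.pi * sigma_inf * r**3)


def grad_u_infinity(dipole: Dipole, sigma_inf: float, points) -> np.ndarray:
    """Gradient of :func:`u_infinity` at ``points``: (m, 3)."""
    R = np.atleast_2d(np.asarray(points, dtype=float)) - dipole.position
    r = np.linalg.norm(R, axis=1)
    if (r == 0).any():
        raise ValueError("evaluation at the dipole singularity")
    q = dipole.moment
    return (
        q[None, :] / r[:, None] ** 3
        - 3.0 * (R @ q)[:, None] * R / r[:, None] ** 5
    ) / (4.0 * np.pi * sigma_inf)


def _volume_quadrature(mesh: Mesh, ids, order):
    """Global quad points (m,Q,3), weights incl. |J| (m,Q) for elements ids."""
    verts = mesh.element_vertices(ids)
    if mesh.element_kind == "tetrahedron":
        ref, w = tet_rule(order)  # unit tet, weights sum 1/6
        grads, vol = tet_gradients(verts)
        e = verts[:, 1:] - verts[:, :1]  # (m,3,3) rows = edges
        pts = verts[:, None, 0] + np.einsum("qe,med->mqd", ref, e)
        W = 6.0 * vol[:, None] * w[None, :]
        return pts, W
    ref, w = hex_rule(order)
    phi = hex_shape(ref)  # (Q,8)
    dphi = hex_shape_grad(ref)
    pts = np.einsum("qn,mnd->mqd", phi, verts)
    J = np.einsum("mnd,qne->mqde", verts, dphi)
    W = np.abs(np.linalg.det(J)) * w[None, :]
    return pts, W


def _boundary_quadrature(mesh: Mesh, order):
    """Quadrature on all boundary faces: points (F,Q,3), weights (F,Q),
    outward unit normals (F,3), owning elements (F,)."""
    bf = boundary_faces(mesh)
    em, fm = bf[:, 0], bf[:, 1]
    loc = np.array(mesh.local_faces)
    if mesh.element_kind == "tetrahedron":
        ref, w = triangle_rule(order)
        fv = mesh.vertices[np.take_along_axis(mesh.elements[em], loc[fm], axis=1)]
        t1 = fv[:, 1] - fv[:, 0]
        t2 = fv[:, 2] - fv[:, 0]
        pts = (
            fv[:, None, 0]
            + ref[None, :, 0, None] * t1[:, None]
            + ref[None, :, 1, None] * t2[:, None]
        )
        cr = np.cross(t1, t2)
        W = w[None, :] * np.linalg.norm(cr, axis=1)[:, None]
        n = cr / np.linalg.norm(cr, axis=1)[:, None]
    else:
        ref, w = quad_face_rule(order)
        fv = mesh.vertices[np.take_along_axis(mesh.elements[em], loc[fm], axis=1)]
        u = ref[None, :, 0, None]
        v = ref[None, :, 1, None]
        pts = (
            (1 - u) * (1 - v) * fv[:, None, 0]
            + u * (1 - v) * fv[:, None, 1]
            + u * v * fv[:, None, 2]
            + (1 - u) * v * fv[:, None, 3]
        )
        tu = (1 - v) * (fv[:, None, 1] - fv[:, None, 0]) + v * (
            fv[:, None, 2] - fv[:, None, 3]
        )
        tv = (1 - u) * (fv[:, None, 3] - fv[:, None, 0]) + u * (
            fv[:, None, 2] - fv[:, None, 1]
        )
        cr = np.cross(tu, tv)
        area = np.linalg.norm(cr, axis=2)
        W = w[None, :] * area
        n = (cr / area[..., None]).mean(axis=1)
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
    centers = mesh.element_vertices(em).mean(axis=1)
    fc = fv.mean(axis=1)
    flip = np.einsum("fd,fd->f", n, fc - centers) < 0
    n[flip] = -n[flip]
    return pts, W, n, em


def _basis_values_at_points(mesh: Mesh, elems, pts):
    """Shape values (F,Q,nb) of elements at global points (F,Q,3)."""
    from .mesh import hex_inverse_batch, tet_barycentric_batch

    F, Q, _ = pts.shape
    verts = mesh.element_vertices(elems)
    flat = pts.reshape(F * Q, 3)
    vflat = np.repeat(verts, Q, axis=0)
    if mesh.element_kind == "tetrahedron":
        return tet_barycentric_batch(vflat, flat).reshape(F, Q, 4)
    xi = hex_inverse_batch(vflat, flat)
    return hex_shape(xi).reshape(F, Q, 8)


def subtraction_rhs(vc: VolumeConductor, dipole: Dipole, quad_order: int = 4,
                    element=None, locator=None,
                    iso_tol: float = 1e-8) -> RightHandSide:
    """Full-subtraction source model (dense right-hand side).

    sigma_inf is the isotropic part (mean eigenvalue) of the dipole
    element's tensor; the correction-potential weak form is

        b_i = - int_Omega sigma_corr grad(u_inf) . grad(phi_i)
              - int_dOmega sigma_inf (grad(u_inf) . n) phi_i

    with sigma_corr = sigma - sigma_inf I.  The volume term is restricted
    to elements where sigma_corr is nonzero; in a fully homogeneous
    conductor only the boundary term contributes.  Warns when a neighbor
    of the dipole element violates the local-homogeneity assumption.
    """
    mesh = vc.mesh
    e = _containing_element(vc, dipole, element, locator)
    sig_el = vc.tensors[e]
    sigma_inf = float(np.trace(sig_el)) / 3.0
    if np.abs(sig_el - sigma_inf * np.eye(3)).max() > iso_tol * sigma_inf:
        raise ValueError(
            "subtraction model requires an isotropic conductivity at the "
            "dipole element"
        )
    if mesh.face_neighbors is not None:
        neigh = mesh.face_neighbors[e]
        neigh = neigh[neigh >= 0]
        if len(neigh) and np.abs(vc.tensors[neigh] - sig_el).max() > 1e-12:
            warnings.warn(
                "conductivity varies next to the dipole element; the "
                "subtraction model assumes local homogeneity",
                stacklevel=2,
            )

    b = np.zeros(mesh.n_vertices)
    corr = vc.tensors - sigma_inf * np.eye(3)
    hetero = np.nonzero(
        np.abs(corr).max(axis=(1, 2)) > 1e-14 * sigma_inf
    )[0]

    # volume correction term
    for start in range(0, len(hetero), _CHUNK):
        ids = hetero[start:start + _CHUNK]
        pts, W = _volume_quadrature(mesh, ids, quad_order)
        m, Q, _ = pts.shape
        gu = grad_u_infinity(dipole, sigma_inf, pts.reshape(-1, 3)).reshape(
            m, Q, 3
        )
        sg = np.einsum("mde,mqe->mqd", corr[ids], gu)
        if mesh.element_kind == "tetrahedron":
            grads, _ = tet_gradients(mesh.element_vertices(ids))  # (m,4,3)
            contrib = -np.einsum("mqd,mnd,mq->mn", sg, grads, W)
        else:
            ref, _w = hex_rule(quad_order)
            dphi = hex_shape_grad(ref)  # (Q,8,3)
            verts = mesh.element_vertices(ids)
            J = np.einsum("mnd,qne->mqde", verts, dphi)
            g = np.einsum("qne,mqed->mqnd", dphi, np.linalg.inv(J))
            contrib = -np.einsum("mqd,mqnd,mq->mn", sg, g, W)
        np.add.at(b, mesh.elements[ids], contrib)

    # boundary flux term
    pts, W, n, em = _boundary_quadrature(mesh, quad_order)
    F, Q, _ = pts.shape
    gu = grad_u_infinity(dipole, sigma_inf, pts.reshape(-1, 3)).reshape(F, Q, 3)
    flux = sigma_inf * np.einsum("fqd,fd->fq", gu, n)
    phi = _basis_values_at_points(mesh, em, pts)
    contrib = -np.einsum("fq,fqn,fq->fn", flux, phi, W)
    np.add.at(b, mesh.elements[em], contrib)

    return RightHandSide(
        mesh.n_vertices, "dense", dense_values=b,
        post_process="add-singularity-potential",
    )


def subtraction_postprocess(potentials, dipole: Dipole, sigma_inf: float,
                            electrode_positions, do_demean: bool = True
                            ) -> np.ndarray:
    """Add the singularity potential to correction-potential readings."""
    out = np.asarray(potentials, dtype=float) + u_infinity(
        dipole, sigma_inf, electrode_positions
    )
    return demean(out) if do_demean else out


# ---------------------------------------------------------------------------
# Whitney

_TET_EDGES = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def whitney_rhs(vc: VolumeConductor, dipole: Dipole, element=None,
                locator=None, weight_floor: float = 1e-12) -> RightHandSide:
    """Whitney source model: the dipole current is represented in the
    lowest-order edge space of the containing tetrahedron.

    Edge coefficients are the weighted-minimum-norm solution that matches
    the represented moment int j^p_h = q exactly, with barycentric
    position weights lambda_i(x_dp) lambda_j(x_dp) favoring edges close
    to the dipole.  Tetrahedral meshes only.
    """
    mesh = vc.mesh
    if mesh.element_kind != "tetrahedron":
        raise ValueError(
            "the Whitney source model is only implemented for tetrahedral "
            "meshes"
        )
    e = _containing_element(vc, dipole, element, locator)
    lam, inside = local_coordinates(mesh, e, dipole.position)
    if not inside:
        raise ValueError("dipole position not inside the located element")
    verts = mesh.vertices[mesh.elements[e]]
    grads, vol = tet_gradients(verts[None])
    grads, vol = grads[0], float(vol[0])
    # integral of each Whitney edge function over the tet
    M = np.stack(
        [vol / 4.0 * (grads[j] - grads[i]) for i, j in _TET_EDGES], axis=1
    )  # (3, 6)
    w = np.array([lam[i] * lam[j] for i, j in _TET_EDGES]) + weight_floor
    Om = np.diag(w / w.sum())
    c = Om @ M.T @ np.linalg.solve(M @ Om @ M.T, dipole.moment)
    # b_i = sum_e c_e int w_e . grad(lambda_i) = sum_e c_e V/4 grad(lambda_i).(g_j - g_i)
    b = np.zeros(4)
    for ce, (i, j) in zip(c, _TET_EDGES):
        b += ce * vol / 4.0 * (grads @ (grads[j] - grads[i]))
    return RightHandSide(mesh.n_vertices, "sparse", mesh.elements[e].copy(), b)


def represented_moment(vc: VolumeConductor, dipole: Dipole, element=None,
                       locator=None) -> np.ndarray:
    """int j^p_h for the Whitney representation (oracle for tests)."""
    mesh = vc.mesh
    e = _containing_element(vc, dipole, element, locator)
    lam, _ = local_coordinates(mesh, e, dipole.position)
    verts = mesh.vertices[mesh.elements[e]]
    grads, vol = tet_gradients(verts[None])
    grads, vol = grads[0], float(vol[0])
    M = np.stack(
        [vol / 4.0 * (grads[j] - grads[i]) for i, j in _TET_EDGES], axis=1
    )
    w = np.array([lam[i] * lam[j] for i, j in _TET_EDGES]) + 1e-12
    Om = np.diag(w / w.sum())
    c = Om @ M.T @ np.linalg.solve(M @ Om @ M.T, dipole.moment)
    return M @ c


# ---------------------------------------------------------------------------
# the source-model interface (bind / assemble / post-process)


class SourceModel:
    """Runtime-selectable source model bound to a volume conductor.

    Mirrors a bind -> assemble-right-hand-side -> post-process life
    cycle: :meth:`bind` locates the dipole element, :meth:`assemble_rhs`
    builds the source vector, and :meth:`post_process` maps raw sensor
    readings of the discrete solution to full potentials (identity for
    direct models; adds u_inf for the subtraction model unless disabled).
    """

    DIRECT = ("partial_integration", "venant", "whitney")

    def __init__(self, name: str, vc: VolumeConductor, space=None,
                 post_process: bool = True, locator=None, **params):
        if name not in (*self.DIRECT, "subtraction"):
            raise ValueError(f"unknown source model {name!r}")
        if isinstance(space, DGSpace) and name != "partial_integration":
            raise ValueError(
                f"the {name} source model is not available for the DG "
                "discretization"
            )
        if name == "whitney" and vc.mesh.element_kind != "tetrahedron":
            raise ValueError(
                "the Whitney source model is only implemented for "
                "tetrahedral meshes"
            )
        self.name = name
        self.vc = vc
        self.space = space if space is not None else CGSpace(vc.mesh)
        self.do_post_process = bool(post_process)
        self.locator = locator if locator is not None else build_center_index(
            vc.mesh
        )
        self.params = params
        self._element = None
        self._sigma_inf = None

    @property
    def is_sparse(self) -> bool:
        return self.name in self.DIRECT

    def bind(self, dipole: Dipole) -> int:
        self._element = _containing_element(
            self.vc, dipole, locator=self.locator
        )
        if self.name == "subtraction":
            self._sigma_inf = float(np.trace(self.vc.tensors[self._element])) / 3.0
        return self._element

    def assemble_rhs(self, dipole: Dipole) -> RightHandSide:
        if self._element is None:
            self.bind(dipole)
        e = self._element
        if self.name == "partial_integration":
            return partial_integration_rhs(
                self.vc, dipole, space=self.space, element=e
            )
        if self.name == "venant":
            return venant_rhs(self.vc, dipole, element=e, **self.params)
        if self.name == "whitney":
            return whitney_rhs(self.vc, dipole, element=e, **self.params)
        return subtraction_rhs(self.vc, dipole, element=e, **self.params)

    def post_process(self, potentials, dipole: Dipole, electrode_positions
                     ) -> np.ndarray:
        if self.name == "subtraction" and self.do_post_process:
            return subtraction_postprocess(
                potentials, dipole, self._sigma_inf, electrode_positions
            )
        return demean(np.asarray(potentials, dtype=float))


def make_source_model(name: str, vc: VolumeConductor, **kwargs) -> SourceModel:
    return SourceModel(name, vc, **kwargs)
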