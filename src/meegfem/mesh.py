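"""Mesh and conductivity data model plus element geometry.

A :class:`Mesh` is a conforming tessellation of the head domain into
tetrahedra or hexahedra with a non-negative integer tissue label per
element.  A :class:`VolumeConductor` pairs the mesh with a symmetric
positive-definite 3x3 conductivity tensor per element.  The library is
unit-agnostic: positions, conductivities and dipole moments only have to
be mutually consistent (the bundled fixtures use SI units: m, S/m, A*m).

Vertex ordering follows the gmsh conventions: tetrahedra are MSH type 4,
hexahedra MSH type 5 with local corners (0,0,0),(1,0,0),(1,1,0),(0,1,0),
(0,0,1),(1,0,1),(1,1,1),(0,1,1) in reference coordinates [0,1]^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quadrature import hex_rule

#: no-neighbor marker in face adjacency
NONE_NEIGHBOR = -1

#: containment tolerance, relative to the element diameter
EPS_LOC = 1e-10

# Tet face i is opposite local vertex i, ordered so the right-hand normal
# points outward.
TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))

# Hex faces in reference coordinates: z=0, z=1, y=0, y=1, x=0, x=1.
HEX_FACES = (
    (0, 3, 2, 1),
    (4, 5, 6, 7),
    (0, 1, 5, 4),
    (3, 7, 6, 2),
    (0, 4, 7, 3),
    (1, 2, 6, 5),
)

#: reference-cube corners matching the MSH type-5 vertex order
HEX_CORNERS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)


def hex_shape(xi):
    """Trilinear Q1 shape values at reference points ``xi`` (...,3) -> (...,8)."""
    xi = np.asarray(xi, dtype=float)
    c = HEX_CORNERS  # (8,3)
    x = xi[..., None, :]  # (...,1,3)
    f = np.where(c > 0.5, x, 1.0 - x)  # (...,8,3)
    return np.prod(f, axis=-1)


def hex_shape_grad(xi):
    """Gradients of the Q1 shapes w.r.t. reference coords: (...,8,3)."""
    xi = np.asarray(xi, dtype=float)
    c = HEX_CORNERS
    x = xi[..., None, :]  # (...,1,3)
    f = np.where(c > 0.5, x, 1.0 - x)  # (...,8,3)
    s = np.where(c > 0.5, 1.0, -1.0)  # (8,3)
    out = np.empty(np.broadcast_shapes(f.shape), dtype=float)
    for d in range(3):
        others = [k for k in range(3) if k != d]
        out[..., d] = s[..., d] * f[..., others[0]] * f[..., others[1]]
    return out


def tet_gradients(verts):
    """P1 barycentric gradients and volumes for tet vertex arrays (...,4,3).

    Returns (grads (...,4,3), volume (...)).  Gradients are constant per
    element; ``grads[i]`` is the gradient of the barycentric coordinate
    attached to local vertex i.
    """
    verts = np.asarray(verts, dtype=float)
    e = verts[..., 1:, :] - verts[..., :1, :]  # (...,3,3) rows edges
    det = np.linalg.det(e)
    # grad(lambda_j) rows W satisfy W e^t = I  (lambda_j(v_i) = delta_ij)
    g = np.linalg.inv(np.swapaxes(e, -1, -2))
    g0 = -g.sum(axis=-2, keepdims=True)
    grads = np.concatenate([g0, g], axis=-2)
    return grads, np.abs(det) / 6.0


@dataclass
class Mesh:
    """Conforming tetrahedral or hexahedral tessellation.

    Parameters
    ----------
    element_kind : {"tetrahedron", "hexahedron"}
    vertices : (nv, 3) float array
    elements : (ne, 4|8) int array of vertex indices (0-based)
    labels : (ne,) non-negative int tissue labels
    face_neighbors : (ne, nf) int array, ``NONE_NEIGHBOR`` on boundary
        faces; populated by :func:`build_face_neighbors`.
    """

    element_kind: str
    vertices: np.ndarray
    elements: np.ndarray
    labels: np.ndarray
    face_neighbors: np.ndarray | None = field(default=None)

    def __post_init__(self):
        if self.element_kind not in ("tetrahedron", "hexahedron"):
            raise ValueError(f"unknown element kind {self.element_kind!r}")
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.int64)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int64)
        nb = 4 if self.element_kind == "tetrahedron" else 8
        if self.elements.ndim != 2 or self.elements.shape[1] != nb:
            raise ValueError("element connectivity has wrong arity")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.vertices)
        ):
            raise ValueError("element refers to invalid vertex index")
        if (self.labels < 0).any():
            raise ValueError("negative tissue label")
        if len(self.labels) != len(self.elements):
            raise ValueError("labels/elements length mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def nodes_per_element(self) -> int:
        return 4 if self.element_kind == "tetrahedron" else 8

    @property
    def faces_per_element(self) -> int:
        return 4 if self.element_kind == "tetrahedron" else 6

    @property
    def local_faces(self):
        return TET_FACES if self.element_kind == "tetrahedron" else HEX_FACES

    def element_vertices(self, ids=None) -> np.ndarray:
        """Vertex coordinate array (ne, nb, 3), optionally for a subset."""
        el = self.elements if ids is None else self.elements[ids]
        return self.vertices[el]

    def element_centers(self) -> np.ndarray:
        return self.element_vertices().mean(axis=1)

    def element_diameters(self) -> np.ndarray:
        v = self.element_vertices()
        d = np.linalg.norm(v[:, :, None, :] - v[:, None, :, :], axis=-1)
        return d.max(axis=(1, 2))

    def element_volumes(self) -> np.ndarray:
        if self.element_kind == "tetrahedron":
            _, vol = tet_gradients(self.element_vertices())
            return vol
        pts, w = hex_rule(2)
        dphi = hex_shape_grad(pts)  # (Q,8,3)
        vols = np.zeros(self.n_elements)
        for start in range(0, self.n_elements, 20000):
            v = self.element_vertices(slice(start, start + 20000))
            J = np.einsum("mnd,qne->mqde", v, dphi)
            det = np.abs(np.linalg.det(J))  # (m,Q)
            vols[start:start + len(v)] = det @ w
        return vols


def build_face_neighbors(mesh: Mesh) -> Mesh:
    """Populate ``mesh.face_neighbors`` by hashing sorted face vertex tuples.

    Boundary faces get :data:`NONE_NEIGHBOR`.  Raises on non-conforming
    meshes (a face shared by more than two elements).
    """
    faces: dict = {}
    nf = mesh.faces_per_element
    neigh = np.full((mesh.n_elements, nf), NONE_NEIGHBOR, dtype=np.int64)
    for e in range(mesh.n_elements):
        conn = mesh.elements[e]
        for f, loc in enumerate(mesh.local_faces):
            key = tuple(sorted(int(conn[i]) for i in loc))
            prev = faces.get(key)
            if prev is None:
                faces[key] = (e, f)
            elif prev == "paired":
                raise ValueError(
                    "non-conforming mesh: face shared by >2 elements"
                )
            else:
                oe, of = prev
                neigh[oe, of] = e
                neigh[e, f] = oe
                faces[key] = "paired"
    mesh.face_neighbors = neigh
    return mesh


def element_geometry(mesh: Mesh, e: int) -> dict:
    """Volume, center, face centers and outer unit face normals of element ``e``."""
    verts = mesh.vertices[mesh.elements[e]]
    center = verts.mean(axis=0)
    if mesh.element_kind == "tetrahedron":
        _, vol = tet_gradients(verts[None])
        volume = float(vol[0])
    else:
        pts, w = hex_rule(2)
        dphi = hex_shape_grad(pts)
        J = np.einsum("nd,qne->qde", verts, dphi)
        volume = float(np.abs(np.linalg.det(J)) @ w)
    if volume <= 0 or not np.isfinite(volume):
        raise ValueError(f"degenerate element {e}")
    centers = []
    normals = []
    for loc in mesh.local_faces:
        fv = verts[list(loc)]
        fc = fv.mean(axis=0)
        if len(loc) == 3:
            n = np.cross(fv[1] - fv[0], fv[2] - fv[0])
        else:
            n = np.cross(fv[2] - fv[0], fv[3] - fv[1])
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError(f"degenerate face on element {e}")
        n = n / nn
        if np.dot(n, fc - center) < 0:
            n = -n
        centers.append(fc)
        normals.append(n)
    return {
        "volume": volume,
        "center": center,
        "face_centers": np.array(centers),
        "face_normals": np.array(normals),
    }


def _tet_barycentric(verts, point):
    g, _ = tet_gradients(verts[None])
    g = g[0]
    lam = np.empty(4)
    lam[1:] = g[1:] @ (point - verts[0])
    lam[0] = 1.0 - lam[1:].sum()
    return lam


def _hex_inverse(verts, point, tol=1e-12, maxiter=50):
    """Invert the trilinear map of one hex by damped Newton iteration."""
    scale = np.linalg.norm(verts.max(axis=0) - verts.min(axis=0))
    xi = np.full(3, 0.5)
    r = hex_shape(xi) @ verts - point
    for _ in range(maxiter):
        if np.linalg.norm(r) <= tol * scale:
            return xi
        J = np.einsum("nd,ne->de", verts, hex_shape_grad(xi))
        try:
            step = np.linalg.solve(J, r)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Jacobian in trilinear inverse") from exc
        t = 1.0
        while t > 1.0 / 64.0:
            cand = xi - t * step
            rc = hex_shape(cand) @ verts - point
            if np.linalg.norm(rc) < np.linalg.norm(r):
                xi, r = cand, rc
                break
            t *= 0.5
        else:
            xi = xi - step
            r = hex_shape(xi) @ verts - point
    if np.linalg.norm(r) > tol * scale * 10:
        raise RuntimeError("trilinear inverse did not converge")
    return xi


def tet_barycentric_batch(verts, pts):
    """Barycentric coords for paired arrays verts (M,4,3), pts (M,3) -> (M,4)."""
    g, _ = tet_gradients(verts)
    lam = np.empty((len(pts), 4))
    lam[:, 1:] = np.einsum("mnd,md->mn", g[:, 1:], pts - verts[:, 0])
    lam[:, 0] = 1.0 - lam[:, 1:].sum(axis=1)
    return lam


def hex_inverse_batch(verts, pts, tol=1e-13, maxiter=30):
    """Batched plain-Newton trilinear inverse: verts (M,8,3), pts (M,3) -> (M,3)."""
    xi = np.full_like(pts, 0.5)
    for _ in range(maxiter):
        r = np.einsum("mn,mnd->md", hex_shape(xi), verts) - pts
        if np.abs(r).max() <= tol:
            break
        J = np.einsum("mnd,mne->mde", verts, hex_shape_grad(xi))
        xi = xi - np.linalg.solve(J, r[..., None])[..., 0]
    return xi


def local_coordinates(mesh: Mesh, e: int, point, eps: float = EPS_LOC):
    """Local coordinates of ``point`` in element ``e`` and a containment flag.

    Tetrahedra return barycentric coordinates (4,), hexahedra reference
    coordinates (3,) in [0,1]^3.  Containment is tolerance-inclusive with
    ``eps`` relative to 1 in local coordinates.
    """
    point = np.asarray(point, dtype=float)
    verts = mesh.vertices[mesh.elements[e]]
    if mesh.element_kind == "tetrahedron":
        lam = _tet_barycentric(verts, point)
        inside = bool((lam >= -eps).all() and (lam <= 1.0 + eps).all())
        return lam, inside
    xi = _hex_inverse(verts, point)
    inside = bool((xi >= -eps).all() and (xi <= 1.0 + eps).all())
    return xi, inside


def shape_values(mesh: Mesh, local) -> np.ndarray:
    """Nodal shape-function values at local coordinates."""
    local = np.asarray(local, dtype=float)
    if mesh.element_kind == "tetrahedron":
        return local
    return hex_shape(local)


@dataclass
class VolumeConductor:
    """Mesh plus per-element symmetric positive-definite conductivity tensors."""

    mesh: Mesh
    tensors: np.ndarray  # (ne, 3, 3)

    def __post_init__(self):
        self.tensors = np.ascontiguousarray(self.tensors, dtype=float)
        if self.tensors.shape != (self.mesh.n_elements, 3, 3):
            raise ValueError("tensor array must be (n_elements, 3, 3)")
        sym = np.abs(self.tensors - np.swapaxes(self.tensors, 1, 2))
        scale = np.abs(self.tensors).max(axis=(1, 2))
        if (sym.max(axis=(1, 2)) > 1e-12 * np.maximum(scale, 1e-300)).any():
            raise ValueError("conductivity tensor not symmetric")
        ev = np.linalg.eigvalsh(self.tensors)
        if (ev <= 0).any():
            raise ValueError("conductivity tensor not positive definite")

    @classmethod
    def from_label_values(cls, mesh: Mesh, values_by_label: dict) -> "VolumeConductor":
        """Build tensors from a label -> scalar or (3,3) tensor mapping."""
        tensors = np.empty((mesh.n_elements, 3, 3))
        for lab in np.unique(mesh.labels):
            try:
                val = values_by_label[int(lab)]
            except KeyError as exc:
                raise ValueError(f"no conductivity for label {lab}") from exc
            t = np.asarray(val, dtype=float)
            if t.ndim == 0:
                t = float(t) * np.eye(3)
            tensors[mesh.labels == lab] = t
        return cls(mesh, tensors)

    def isotropic_part(self) -> np.ndarray:
        """Mean eigenvalue (trace/3) of each element tensor."""
        return np.trace(self.tensors, axis1=1, axis2=2) / 3.0


@dataclass
class Dipole:
    """Current dipole: position x_dp and moment q (source term q . grad delta)."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)
        if np.linalg.norm(self.moment) == 0:
            raise ValueError("dipole moment must be nonzero")
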