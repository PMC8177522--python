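"""Symmetric interior-penalty discontinuous Galerkin (SIPG) discretization.

The bilinear form adds to the elementwise volume terms the interior-face
consistency, symmetry and penalty terms

    - int_F {sigma grad u}.n [v] - int_F {sigma grad v}.n [u]
    + (eta gamma_F / h_F) int_F [u][v]

with conductivity-weighted (harmonic) averages: with delta = n.sigma.n on
either side, the weights are omega_- = delta_+/(delta_-+delta_+) and the
penalty scale gamma_F = 2 delta_- delta_+/(delta_- + delta_+).  The
harmonic weighting keeps the scheme robust across the high-contrast
skull.  Natural (no-flux) boundary conditions add no boundary-face
terms, so constants remain in the kernel and the matrix is symmetric.

Basis functions are the elementwise P1 (tet) / Q1 (hex) shapes; degrees
of freedom are blocked per element (element * nb + local).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .fem import DGSpace, element_stiffness_matrices
from .mesh import (
    NONE_NEIGHBOR,
    Mesh,
    VolumeConductor,
    hex_inverse_batch,
    hex_shape,
    hex_shape_grad,
    tet_barycentric_batch,
    tet_gradients,
)
from .quadrature import quad_face_rule, triangle_rule

_CHUNK = 20000


def interior_faces(mesh: Mesh) -> np.ndarray:
    """(m, 3) array of (minus element, plus element, minus local face) with
    minus < plus so each interior face appears once."""
    if mesh.face_neighbors is None:
        raise ValueError("face neighbors not built")
    el, fa = np.nonzero(mesh.face_neighbors != NONE_NEIGHBOR)
    nb = mesh.face_neighbors[el, fa]
    keep = el < nb
    return np.stack([el[keep], nb[keep], fa[keep]], axis=1)


def _face_quadrature(mesh: Mesh, faces, order=2):
    """Global quad points, weights (incl. area element), and unit normals
    oriented minus -> plus for the faces (em, ep, fm)."""
    em, ep, fm = faces[:, 0], faces[:, 1], faces[:, 2]
    if mesh.element_kind == "tetrahedron":
        ref, w = triangle_rule(order)  # (Q,2)
        loc = np.array(mesh.local_faces)  # (4,3)
        fv = mesh.vertices[
            np.take_along_axis(mesh.elements[em], loc[fm], axis=1)
        ]  # (F,3,3)
        t1 = fv[:, 1] - fv[:, 0]
        t2 = fv[:, 2] - fv[:, 0]
        pts = (
            fv[:, None, 0]
            + ref[None, :, 0, None] * t1[:, None]
            + ref[None, :, 1, None] * t2[:, None]
        )  # (F,Q,3)
        cr = np.cross(t1, t2)
        area2 = np.linalg.norm(cr, axis=1)  # parallelogram area
        W = w[None, :] * area2[:, None]
        n = cr / area2[:, None]
    else:
        ref, w = quad_face_rule(order)  # (Q,2)
        loc = np.array(mesh.local_faces)  # (6,4)
        fv = mesh.vertices[
            np.take_along_axis(mesh.elements[em], loc[fm], axis=1)
        ]  # (F,4,3)
        u = ref[None, :, 0, None]
        v = ref[None, :, 1, None]
        pts = (
            (1 - u) * (1 - v) * fv[:, None, 0]
            + u * (1 - v) * fv[:, None, 1]
            + u * v * fv[:, None, 2]
            + (1 - u) * v * fv[:, None, 3]
        )
        tu = (
            (1 - v) * (fv[:, None, 1] - fv[:, None, 0])
            + v * (fv[:, None, 2] - fv[:, None, 3])
        )
        tv = (
            (1 - u) * (fv[:, None, 3] - fv[:, None, 0])
            + u * (fv[:, None, 2] - fv[:, None, 1])
        )
        cr = np.cross(tu, tv)  # (F,Q,3)
        area = np.linalg.norm(cr, axis=2)
        W = w[None, :] * area
        n = (cr / area[..., None]).mean(axis=1)
        n = n / np.linalg.norm(n, axis=1, keepdims=True)
    # orient minus -> plus
    cm = mesh.element_vertices(em).mean(axis=1)
    cp = mesh.element_vertices(ep).mean(axis=1)
    flip = np.einsum("fd,fd->f", n, cp - cm) < 0
    n[flip] = -n[flip]
    hF = np.linalg.norm(
        fv[:, :, None, :] - fv[:, None, :, :], axis=-1
    ).max(axis=(1, 2))
    return pts, W, n, hF


def _side_basis(mesh: Mesh, elems, pts):
    """Basis values (F,Q,nb) and global gradients (F,Q,nb,3) of the elements
    ``elems`` evaluated at the global points ``pts`` (F,Q,3)."""
    F, Q, _ = pts.shape
    verts = mesh.element_vertices(elems)  # (F,nb,3)
    flat = pts.reshape(F * Q, 3)
    vflat = np.repeat(verts, Q, axis=0)
    if mesh.element_kind == "tetrahedron":
        lam = tet_barycentric_batch(vflat, flat)  # (FQ,4)
        phi = lam.reshape(F, Q, 4)
        grads, _ = tet_gradients(verts)  # (F,4,3) constant
        g = np.broadcast_to(grads[:, None], (F, Q, 4, 3)).copy()
        return phi, g
    xi = hex_inverse_batch(vflat, flat)  # (FQ,3)
    phi = hex_shape(xi).reshape(F, Q, 8)
    dphi = hex_shape_grad(xi)  # (FQ,8,3) local
    J = np.einsum("mnd,mne->mde", vflat, dphi)
    g = np.einsum("mne,med->mnd", dphi, np.linalg.inv(J)).reshape(F, Q, 8, 3)
    return phi, g


def assemble_stiffness_dg(vc: VolumeConductor, eta: float = 4.0,
                          quad_order: int = 2) -> sp.csr_array:
    """Assemble the SIPG stiffness matrix on the DG space.

    ``eta`` is the (positive) penalty parameter; the effective penalty on
    a face scales as ``eta * gamma_F / h_F`` with the harmonic
    conductivity mean gamma_F and the face diameter h_F.
    """
    if eta <= 0:
        raise ValueError("penalty parameter eta must be positive")
    mesh = vc.mesh
    nb = mesh.nodes_per_element
    space = DGSpace(mesh)
    rows, cols, vals = [], [], []

    # volume terms
    for start in range(0, mesh.n_elements, _CHUNK):
        sl = slice(start, min(start + _CHUNK, mesh.n_elements))
        ke = element_stiffness_matrices(vc, sl, quad_order)
        m = ke.shape[0]
        dofs = (
            np.arange(start, start + m)[:, None] * nb + np.arange(nb)[None, :]
        )
        rows.append(np.repeat(dofs, nb, axis=1).ravel())
        cols.append(np.tile(dofs, (1, nb)).ravel())
        vals.append(ke.ravel())

    # interior-face terms
    faces = interior_faces(mesh)
    for start in range(0, len(faces), _CHUNK // 4):
        fc = faces[start:start + _CHUNK // 4]
        em, ep = fc[:, 0], fc[:, 1]
        pts, W, n, hF = _face_quadrature(mesh, fc, quad_order)
        phim, gm = _side_basis(mesh, em, pts)
        phip, gp = _side_basis(mesh, ep, pts)
        sm = vc.tensors[em]  # (F,3,3)
        sp_ = vc.tensors[ep]
        dm = np.einsum("fd,fde,fe->f", n, sm, n)
        dp = np.einsum("fd,fde,fe->f", n, sp_, n)
        wsum = dm + dp
        om = dp / wsum
        op = dm / wsum
        gamma = 2.0 * dm * dp / wsum
        # jump-signed values and weighted normal fluxes, stacked over sides
        jump = np.concatenate([phim, -phip], axis=2)  # (F,Q,2nb)
        flux_m = om[:, None, None] * np.einsum(
            "fde,fqne,fd->fqn", sm, gm, n
        )
        flux_p = op[:, None, None] * np.einsum(
            "fde,fqne,fd->fqn", sp_, gp, n
        )
        flux = np.concatenate([flux_m, flux_p], axis=2)
        pen = (eta * gamma / hF)[:, None, None]
        K = (
            -np.einsum("fqi,fqj,fq->fij", flux, jump, W)
            - np.einsum("fqi,fqj,fq->fij", jump, flux, W)
            + pen * np.einsum("fqi,fqj,fq->fij", jump, jump, W)
        )
        dm_dofs = em[:, None] * nb + np.arange(nb)[None, :]
        dp_dofs = ep[:, None] * nb + np.arange(nb)[None, :]
        dofs = np.concatenate([dm_dofs, dp_dofs], axis=1)  # (F,2nb)
        rows.append(np.repeat(dofs, 2 * nb, axis=1).ravel())
        cols.append(np.tile(dofs, (1, 2 * nb)).ravel())
        vals.append(K.ravel())

    A = sp.coo_array(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(space.ndof, space.ndof),
    ).tocsr()
    A.sum_duplicates()
    return A
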