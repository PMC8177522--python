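"""Gauss quadrature rules on reference elements.

Reference elements: the unit cube [0,1]^3 (hexahedra, tensor-product
Gauss-Legendre), the unit simplex {x,y,z >= 0, x+y+z <= 1} (tetrahedra,
collapsed-coordinate Gauss-Jacobi so the Duffy Jacobian is integrated
exactly), and their 2D faces.  ``order`` is the polynomial degree that is
integrated exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import roots_jacobi, roots_legendre


def _npoints(order: int) -> int:
    # n Gauss points are exact to degree 2n-1
    return max(1, (int(order) + 2) // 2)


def _gauss01(order: int):
    """Gauss-Legendre points/weights on [0,1]."""
    x, w = roots_legendre(_npoints(order))
    return 0.5 * (x + 1.0), 0.5 * w


def _gauss_jacobi01(order: int, alpha: int):
    """Points/weights for integral of (1-u)^alpha f(u) on [0,1]."""
    t, w = roots_jacobi(_npoints(order), alpha, 0.0)
    return 0.5 * (t + 1.0), w * 0.5 ** (alpha + 1)


def interval_rule(order: int):
    return _gauss01(order)


def hex_rule(order: int):
    """Tensor Gauss rule on [0,1]^3; returns (Q,3) points, (Q,) weights."""
    x, w = _gauss01(order)
    P = np.stack(np.meshgrid(x, x, x, indexing="ij"), axis=-1).reshape(-1, 3)
    W = (w[:, None, None] * w[None, :, None] * w[None, None, :]).reshape(-1)
    return P, W


def quad_face_rule(order: int):
    """Tensor Gauss rule on the unit square [0,1]^2."""
    x, w = _gauss01(order)
    P = np.stack(np.meshgrid(x, x, indexing="ij"), axis=-1).reshape(-1, 2)
    W = (w[:, None] * w[None, :]).reshape(-1)
    return P, W


def tet_rule(order: int):
    """Collapsed (Duffy) Gauss rule on the unit tetrahedron.

    Uses x = u, y = v(1-u), z = w(1-u)(1-v) with Jacobian (1-u)^2 (1-v);
    the Jacobian factors are absorbed in Gauss-Jacobi weights, so the rule
    is exact for total degree <= ``order`` polynomials.
    """
    u, wu = _gauss_jacobi01(order, 2)
    v, wv = _gauss_jacobi01(order, 1)
    z, wz = _gauss01(order)
    U, V, Z = np.meshgrid(u, v, z, indexing="ij")
    X = U
    Y = V * (1.0 - U)
    ZZ = Z * (1.0 - U) * (1.0 - V)
    W = (wu[:, None, None] * wv[None, :, None] * wz[None, None, :])
    P = np.stack([X.reshape(-1), Y.reshape(-1), ZZ.reshape(-1)], axis=-1)
    return P, W.reshape(-1)


def triangle_rule(order: int):
    """Collapsed Gauss rule on the unit triangle {x,y >= 0, x+y <= 1}."""
    u, wu = _gauss_jacobi01(order, 1)
    v, wv = _gauss01(order)
    U, V = np.meshgrid(u, v, indexing="ij")
    P = np.stack([U.reshape(-1), (V * (1.0 - U)).reshape(-1)], axis=-1)
    W = (wu[:, None] * wv[None, :]).reshape(-1)
    return P, W
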