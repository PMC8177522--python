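"""Quasi-analytic reference solutions in concentric multilayer spheres.

``sphere_eeg`` evaluates the Legendre-series surface potential of a
current dipole inside a stack of concentric isotropic shells with a
no-flux outer boundary; it is the oracle the FEM potentials converge to.
``sarvas_meg`` is the closed-form exterior magnetic field of a dipole in
a spherically symmetric conductor (independent of the conductivity
profile; identically zero for radial dipoles).  ``rdm``/``lnmag`` are
the standard topography and magnitude error metrics.

Series construction: the dipole is rotated onto the z-axis and its
moment split into a radial and a tangential component.  In the innermost
region the potential is the unbounded-medium expansion of u_inf plus a
regular correction A_L r^n; every outer shell carries A_j r^n +
B_j r^-(n+1).  Continuity of u and of the radial current sigma du/dr at
each interface plus the outer Neumann condition give a small linear
system per harmonic degree n, solved with radii scaled by the outer
radius for conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, lpmv

from .mesh import Dipole

MU0_OVER_4PI = 1e-7  # SI


@dataclass
class SphereModel:
    """Concentric shells: radii strictly decreasing (outermost first),
    one positive isotropic conductivity per shell."""

    center: np.ndarray
    radii: np.ndarray
    conductivities: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.conductivities = np.asarray(
            self.conductivities, dtype=float
        ).reshape(-1)
        if len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must pair up")
        if (np.diff(self.radii) >= 0).any() or (self.radii <= 0).any():
            raise ValueError("radii must be strictly decreasing and positive")
        if (self.conductivities <= 0).any():
            raise ValueError("conductivities must be positive")


def _shell_coefficients(model: SphereModel, n: int):
    """Per-degree radial coefficients for unit source strength.

    Returns (a, bvec): region-j potential is a[j] r^n + bvec[j] r^-(n+1)
    plus, in the innermost region, the source term 1 * r^-(n+1), all in
    radii scaled by the outer radius.
    """
    r = model.radii / model.radii[0]
    sig = model.conductivities
    L = len(r)
    # unknowns: A_1, B_1, ..., A_{L-1}, B_{L-1}, A_L  (B_L = 0; source S=1)
    m = 2 * L - 1
    M = np.zeros((m, m))
    rhs = np.zeros(m)

    def idx_a(j):  # 0-based region j
        return 2 * j

    def idx_b(j):
        return 2 * j + 1

    # outer boundary: sigma_1 du/dr = 0 at r=1
    row = 0
    M[row, idx_a(0)] = n
    if L > 1:
        M[row, idx_b(0)] = -(n + 1)
    else:
        rhs[row] = (n + 1)  # moves source term to the right-hand side
    row += 1
    # interfaces r_k between region k (outer) and k+1 (inner), k=0..L-2
    for k in range(L - 1):
        rk = r[k + 1]
        inner_is_last = k + 1 == L - 1
        # continuity of u
        M[row, idx_a(k)] = rk**n
        M[row, idx_b(k)] = rk ** -(n + 1)
        M[row, idx_a(k + 1)] -= rk**n
        if not inner_is_last:
            M[row, idx_b(k + 1)] -= rk ** -(n + 1)
        else:
            rhs[row] = rk ** -(n + 1)  # source term of the innermost region
        row += 1
        # continuity of sigma du/dr
        M[row, idx_a(k)] = sig[k] * n * rk ** (n - 1)
        M[row, idx_b(k)] = -sig[k] * (n + 1) * rk ** -(n + 2)
        M[row, idx_a(k + 1)] -= sig[k + 1] * n * rk ** (n - 1)
        if not inner_is_last:
            M[row, idx_b(k + 1)] += sig[k + 1] * (n + 1) * rk ** -(n + 2)
        else:
            rhs[row] = -sig[k + 1] * (n + 1) * rk ** -(n + 2)
        row += 1
    sol = np.linalg.solve(M, rhs)
    a = sol[0::2][:L]
    b = np.zeros(L)
    b[: L - 1] = sol[1::2]
    return a, b


def sphere_eeg(model: SphereModel, dipole: Dipole, points, n_max: int = 200,
               rtol: float = 1e-12, demean: bool = True) -> np.ndarray:
    """Series potential of ``dipole`` at ``points`` in/on the multilayer
    sphere (typically the outer surface; any radius outside the dipole
    radius works, e.g. for boundary-condition checks).

    Truncates at degree ``n_max`` or when the relative term increment
    drops below ``rtol``.  ``demean=False`` returns the raw series (whose
    additive constant is fixed by the vanishing monopole term).
    """
    R0 = model.radii[0]
    x0 = (dipole.position - model.center) / R0
    pts = (np.atleast_2d(np.asarray(points, dtype=float)) - model.center) / R0
    b = np.linalg.norm(x0)
    rs = model.radii / R0  # descending, rs[0] = 1
    L = len(rs)
    if b >= rs[-1]:
        raise ValueError("dipole must lie strictly inside the innermost shell")
    q = dipole.moment
    sigL = model.conductivities[-1]
    if b < 1e-14:
        zhat = q / np.linalg.norm(q)
        q_r = float(np.linalg.norm(q))
        q_t = 0.0
        xhat = np.zeros(3)
    else:
        zhat = x0 / b
        q_r = float(q @ zhat)
        qt_vec = q - q_r * zhat
        q_t = float(np.linalg.norm(qt_vec))
        xhat = qt_vec / q_t if q_t > 0 else np.zeros(3)

    r = np.linalg.norm(pts, axis=1)
    if (r <= b).any():
        raise ValueError("evaluation points must lie outside the dipole radius")
    rhat = pts / r[:, None]
    cost = np.clip(rhat @ zhat, -1.0, 1.0)
    # region index per point (0 = outermost shell)
    reg = np.clip((r[:, None] <= rs[None, :] * (1 + 1e-12)).sum(axis=1) - 1,
                  0, L - 1)
    innermost = reg == L - 1
    # azimuth of the evaluation point in the dipole frame
    if q_t > 0:
        cosphi = (rhat @ xhat) / np.maximum(
            np.sqrt(1.0 - cost**2), 1e-300
        )
        # guard: on the axis the P_n^1 factor vanishes anyway
        cosphi = np.clip(cosphi, -1.0, 1.0)
    else:
        cosphi = np.zeros_like(cost)

    out = np.zeros(len(pts))
    scale_max = 0.0
    for n in range(1, n_max + 1):
        a_r, b_r = _shell_coefficients(model, n)
        # radial factor for unit source strength in each point's region
        f = a_r[reg] * r**n + b_r[reg] * r ** -(n + 1)
        f = f + np.where(innermost, r ** -(n + 1), 0.0)
        # source strengths of the u_inf expansion, scaled radii
        s_rad = q_r * n * b ** (n - 1) / (4.0 * np.pi * sigL)
        s_tan = -q_t * b ** (n - 1) / (4.0 * np.pi * sigL)
        term = s_rad * f * eval_legendre(n, cost)
        if q_t != 0.0:
            term = term + s_tan * f * lpmv(1, n, cost) * cosphi
        out += term
        tmax = np.abs(term).max()
        scale_max = max(scale_max, np.abs(out).max())
        if n > 2 and tmax < rtol * max(scale_max, 1e-300):
            break
    out = out / R0**2  # undo the length scaling (potential ~ 1/length^2)
    if demean:
        out = out - out.mean()
    return out


def u_infinity_series(dipole: Dipole, sigma: float, points,
                      n_max: int = 200) -> np.ndarray:
    """Multipole expansion of the unbounded-medium dipole potential.

    Valid for evaluation radii larger than the dipole radius (both
    measured from the origin).  Used as an independent consistency
    oracle for the shell-series source coefficients.
    """
    x0 = np.asarray(dipole.position, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    b = np.linalg.norm(x0)
    q = dipole.moment
    if b < 1e-14:
        zhat = q / np.linalg.norm(q)
        q_r, q_t = float(np.linalg.norm(q)), 0.0
        xhat = np.zeros(3)
    else:
        zhat = x0 / b
        q_r = float(q @ zhat)
        qt_vec = q - q_r * zhat
        q_t = float(np.linalg.norm(qt_vec))
        xhat = qt_vec / q_t if q_t > 0 else np.zeros(3)
    r = np.linalg.norm(pts, axis=1)
    if (r <= b).any():
        raise ValueError("points must lie outside the dipole radius")
    rhat = pts / r[:, None]
    cost = np.clip(rhat @ zhat, -1.0, 1.0)
    if q_t > 0:
        cosphi = np.clip(
            (rhat @ xhat) / np.maximum(np.sqrt(1.0 - cost**2), 1e-300),
            -1.0, 1.0,
        )
    else:
        cosphi = np.zeros_like(cost)
    out = np.zeros(len(pts))
    for n in range(1, n_max + 1):
        s_rad = q_r * n * b ** (n - 1) / (4.0 * np.pi * sigma)
        s_tan = -q_t * b ** (n - 1) / (4.0 * np.pi * sigma)
        radial = r ** -(n + 1)
        term = s_rad * radial * eval_legendre(n, cost)
        if q_t != 0.0:
            term = term + s_tan * radial * lpmv(1, n, cost) * cosphi
        out += term
    return out


def sarvas_meg(center, dipole: Dipole, coils) -> np.ndarray:
    """Closed-form exterior field of a dipole in a spherical conductor,
    projected on the coil directions.

    Independent of the (spherically symmetric) conductivity profile;
    exactly zero for radial dipoles.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    x0 = dipole.position - center
    q = dipole.moment
    out = np.empty(len(coils.positions))
    for j, (y, d) in enumerate(zip(coils.positions, coils.directions)):
        yv = y - center
        r = np.linalg.norm(yv)
        if r <= np.linalg.norm(x0):
            raise ValueError("coil must lie outside the dipole radius")
        a_vec = yv - x0
        a = np.linalg.norm(a_vec)
        F = a * (r * a + r**2 - x0 @ yv)
        gradF = (
            (a**2 / r + (a_vec @ yv) / a + 2.0 * a + 2.0 * r) * yv
            - (a + 2.0 * r + (a_vec @ yv) / a) * x0
        )
        qxx0 = np.cross(q, x0)
        B = MU0_OVER_4PI / F**2 * (F * qxx0 - (qxx0 @ yv) * gradF)
        out[j] = B @ d
    return out


def rdm(a, b) -> float:
    """Relative difference measure ||a/||a|| - b/||b||||_2, in [0, 2]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("rdm undefined for zero vectors")
    return float(np.linalg.norm(a / na - b / nb))


def lnmag(a, b) -> float:
    """Logarithmic magnitude error ln(||a|| / ||b||)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("lnmag undefined for zero vectors")
    return float(np.log(na / nb))
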