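"""Single-dipole deviation scan with a normal constraint.

For every source-space location with fixed orientation and unit
strength, the scan fits the optimal nonnegative strength

    s = max(<l, m> / ||l||^2, 0)

of the location's leadfield l against the measurement m (the clamp
restricts the solution to the positive normal direction) and scores it
with the goodness of fit GOF = 1 - ||l s - m||^2 / ||m||^2, which is 1
iff the measurement is reproduced exactly.  Both the measurement and the
leadfield columns are demeaned before fitting, consistent with the EEG
reference (gauge) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import demean


@dataclass
class SourceSpace:
    """Candidate dipole positions with unit surface normals."""

    positions: np.ndarray
    normals: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.normals = np.atleast_2d(np.asarray(self.normals, float))
        if self.positions.shape != self.normals.shape:
            raise ValueError("positions/normals shape mismatch")
        nn = np.linalg.norm(self.normals, axis=1)
        if (np.abs(nn - 1.0) > 1e-10).any():
            raise ValueError("source-space normals must be unit length")

    def __len__(self):
        return len(self.positions)


@dataclass
class ScanResult:
    """Per-location strengths and GOF; ``best`` maximizes GOF (ties ->
    lowest index)."""

    strengths: np.ndarray
    gof: np.ndarray
    best: int
    provenance: dict | None = None


def fit_strength(l, m) -> float:
    """Optimal nonnegative strength of leadfield ``l`` for measurement ``m``."""
    l = np.asarray(l, dtype=float)
    m = np.asarray(m, dtype=float)
    ll = float(l @ l)
    if ll == 0:
        raise ValueError("zero leadfield")
    return max(float(l @ m) / ll, 0.0)


def goodness_of_fit(l, s: float, m) -> float:
    """GOF = 1 - ||l s - m||^2 / ||m||^2 (1 iff exactly reproduced)."""
    l = np.asarray(l, dtype=float)
    m = np.asarray(m, dtype=float)
    mm = float(m @ m)
    if mm == 0:
        raise ValueError("zero measurement")
    r = l * s - m
    return 1.0 - float(r @ r) / mm


def dipole_scan(leadfields, m, provenance: dict | None = None) -> ScanResult:
    """Scan all columns of the p x k leadfield matrix against ``m``.

    The measurement and every column are demeaned before fitting.  Under
    the nonnegativity clamp the GOF is bounded below by 0 (s = 0 leaves
    the measurement untouched).
    """
    L = np.asarray(leadfields, dtype=float)
    m = demean(np.asarray(m, dtype=float))
    if L.ndim != 2 or L.shape[0] != len(m):
        raise ValueError("leadfield/measurement dimension mismatch")
    L = L - L.mean(axis=0, keepdims=True)
    ll = np.einsum("pk,pk->k", L, L)
    if (ll == 0).any():
        raise ValueError("zero leadfield column")
    s = np.maximum((m @ L) / ll, 0.0)
    resid = L * s[None, :] - m[:, None]
    gof = 1.0 - np.einsum("pk,pk->k", resid, resid) / float(m @ m)
    best = int(np.argmax(gof))
    return ScanResult(s, gof, best, provenance)
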