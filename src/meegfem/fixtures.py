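"""Deterministic generators for validation studies.

Voxelized multilayer-sphere volume conductors, their conforming
tetrahedral subdivisions, electrode caps, magnetometer shells and noisy
synthetic measurements — everything the validation and test suites need
without external data.  All generators are pure functions of their
arguments (plus an explicit seed where randomness is involved), so
identical inputs give bit-identical outputs.

The default validation model is a three-shell sphere (skin, skull,
brain) with radii 0.092 / 0.086 / 0.080 m and conductivities
0.33 / 0.0042 / 0.33 S/m.
"""

from __future__ import annotations

import numpy as np

from .meg import CoilSet
from .mesh import Dipole, Mesh, VolumeConductor
from .scan import SourceSpace

DEFAULT_RADII = (0.092, 0.086, 0.080)
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)


def hex_sphere_model(radii=DEFAULT_RADII,
                     conductivities=DEFAULT_CONDUCTIVITIES,
                     voxel_size: float = 0.004,
                     center=(0.0, 0.0, 0.0)) -> VolumeConductor:
    """Voxelized concentric-shell conductor on a regular hexahedral grid.

    Voxels whose centers lie within the outer radius are retained; each
    element is labeled with the innermost shell whose radius still
    reaches its center (label 0 = outermost shell), and gets the
    corresponding isotropic conductivity tensor.
    """
    radii = np.asarray(radii, dtype=float)
    conductivities = np.asarray(conductivities, dtype=float)
    center = np.asarray(center, dtype=float)
    if (np.diff(radii) >= 0).any():
        raise ValueError("radii must be strictly decreasing")
    if len(radii) != len(conductivities):
        raise ValueError("radii and conductivities must pair up")
    h = float(voxel_size)
    R = float(radii[0])
    if h >= R:
        raise ValueError("voxel size must be smaller than the outer radius")
    half = int(np.ceil(R / h))
    idx = np.arange(-half, half)
    I, J, K = np.meshgrid(idx, idx, idx, indexing="ij")
    ijk = np.stack([I.reshape(-1), J.reshape(-1), K.reshape(-1)], axis=1)
    centers = (ijk + 0.5) * h  # voxel centers, grid origin at `center`
    d = np.linalg.norm(centers, axis=1)
    keep = d <= R
    ijk = ijk[keep]
    d = d[keep]
    # innermost shell whose radius >= center distance
    labels = (radii[None, :] >= d[:, None]).sum(axis=1) - 1

    # voxel corner lattice -> unique vertices
    corner_offsets = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ]
    )
    corners = ijk[:, None, :] + corner_offsets[None, :, :]  # (m,8,3)
    flat = corners.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    elements = inverse.reshape(-1, 8)
    vertices = uniq * h + center
    mesh = Mesh("hexahedron", vertices, elements, labels)
    return VolumeConductor.from_label_values(
        mesh, {i: float(c) for i, c in enumerate(conductivities)}
    )


# Kuhn subdivision of the reference cube: six tets around the main
# diagonal v0 -> v6; translation-invariant, hence conforming on a grid.
_KUHN_TETS = (
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
)


def hex_to_tet(vc: VolumeConductor) -> VolumeConductor:
    """Split each hexahedron into six tetrahedra (conforming; labels and
    tensors inherited; total volume preserved)."""
    mesh = vc.mesh
    if mesh.element_kind != "hexahedron":
        raise ValueError("hex_to_tet requires a hexahedral conductor")
    tets = np.concatenate(
        [mesh.elements[:, list(t)] for t in _KUHN_TETS], axis=0
    )
    # interleave so the 6 children of hex e are contiguous
    tets = tets.reshape(6, mesh.n_elements, 4).transpose(1, 0, 2).reshape(-1, 4)
    labels = np.repeat(mesh.labels, 6)
    tensors = np.repeat(vc.tensors, 6, axis=0)
    newmesh = Mesh("tetrahedron", mesh.vertices.copy(), tets, labels)
    return VolumeConductor(newmesh, tensors)


def electrode_cap(n: int, radius: float, center=(0.0, 0.0, 0.0)
                  ) -> np.ndarray:
    """Deterministic golden-angle spiral of ``n`` electrodes on the upper
    hemisphere of the given radius."""
    center = np.asarray(center, dtype=float)
    k = np.arange(n)
    # z from near the pole down to just above the equator
    z = 1.0 - (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    return center + radius * pts


def magnetometer_shell(n: int, radius: float, center=(0.0, 0.0, 0.0)
                       ) -> CoilSet:
    """Fibonacci-spiral magnetometers on a full sphere with radial
    measurement directions."""
    center = np.asarray(center, dtype=float)
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z**2)
    d = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    return CoilSet(center + radius * d, d)


def interior_source_space(n: int, radius: float, center=(0.0, 0.0, 0.0),
                          seed: int = 0) -> SourceSpace:
    """Random source locations inside ``radius`` with radial unit normals
    (a spherical stand-in for a cortical normal constraint)."""
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n - got), 3))
        r = np.linalg.norm(cand, axis=1)
        cand = cand[(r <= 1.0) & (r > 0.2)]
        take = min(len(cand), n - got)
        pts[got:got + take] = cand[:take]
        got += take
    normals = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    return SourceSpace(center + radius * pts, normals)


def synthetic_measurement(leadfield, s_true: float, noise_sd: float,
                          seed: int = 0) -> np.ndarray:
    """Demeaned noisy measurement m = l s_true + N(0, noise_sd^2)."""
    rng = np.random.default_rng(seed)
    l = np.asarray(leadfield, dtype=float)
    m = l * s_true + rng.normal(0.0, noise_sd, size=l.shape)
    return m - m.mean()


def noise_sd_for_snr(signal, snr_db: float) -> float:
    """Noise standard deviation giving the requested SNR (dB, power ratio
    of mean signal power to noise variance)."""
    s = np.asarray(signal, dtype=float)
    p_sig = float(s @ s) / len(s)
    return float(np.sqrt(p_sig / 10.0 ** (snr_db / 10.0)))


def brain_dipole(eccentricity: float, direction, moment,
                 radii=DEFAULT_RADII, center=(0.0, 0.0, 0.0)) -> Dipole:
    """Dipole at the given eccentricity (fraction of the innermost
    radius) along ``direction`` with the given moment vector."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    pos = np.asarray(center, dtype=float) + eccentricity * radii[-1] * direction
    return Dipole(pos, moment)
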