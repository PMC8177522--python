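"""Dipole-element localization.

A k-d tree over the element centers supplies a starting element that is
close to the query point; from there the edge-hopping walk follows face
normals toward the point.  Edge-hopping requires convexity only along
the walk, so a linear search over all elements backs it up whenever the
walk gets stuck (non-convex geometry) or the verification containment
test fails.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import NONE_NEIGHBOR, Mesh, element_geometry, local_coordinates

#: face-plane tolerance, relative to the element diameter
EPS_HOP = 1e-12


class HopStatus(enum.Enum):
    FOUND = "found"
    OUTSIDE = "outside"
    STUCK = "stuck"


@dataclass
class CenterIndex:
    """Nearest-neighbor index over element centers (k-d tree)."""

    tree: cKDTree
    centers: np.ndarray

    def nearest(self, point) -> int:
        _, idx = self.tree.query(np.asarray(point, dtype=float))
        return int(idx)


def build_center_index(mesh: Mesh) -> CenterIndex:
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    centers = mesh.element_centers()
    return CenterIndex(cKDTree(centers), centers)


def edge_hop(mesh: Mesh, start: int, point, count_hops: bool = False):
    """Walk from ``start`` toward ``point`` across element faces.

    Returns ``(status, element)``: FOUND with the containing element,
    OUTSIDE when a boundary face separates the point (the point lies
    outside the mesh or the mesh is not convex there), or STUCK when the
    walk revisits an element.  A FOUND element is verified with the
    containment test of :func:`local_coordinates`.
    """
    if start < 0 or start >= mesh.n_elements:
        raise ValueError(f"invalid start element {start}")
    if mesh.face_neighbors is None:
        raise ValueError("face neighbors not built; call build_face_neighbors")
    point = np.asarray(point, dtype=float)
    visited = set()
    current = int(start)

    def ret(status, elem):
        if count_hops:
            return status, elem, len(visited)
        return status, elem

    while True:
        if current in visited:
            return ret(HopStatus.STUCK, None)
        visited.add(current)
        geo = element_geometry(mesh, current)
        eps = EPS_HOP * np.linalg.norm(
            np.ptp(mesh.vertices[mesh.elements[current]], axis=0)
        )
        hopped = False
        for f in range(mesh.faces_per_element):
            signed = np.dot(point - geo["face_centers"][f], geo["face_normals"][f])
            if signed > eps:
                neighbor = int(mesh.face_neighbors[current, f])
                if neighbor == NONE_NEIGHBOR:
                    return ret(HopStatus.OUTSIDE, None)
                current = neighbor
                hopped = True
                break
        if not hopped:
            _, inside = local_coordinates(mesh, current, point)
            if not inside:
                return ret(HopStatus.STUCK, None)
            return ret(HopStatus.FOUND, current)


def linear_locate(mesh: Mesh, point):
    """O(n) scan: first element in storage order containing ``point``, or None."""
    point = np.asarray(point, dtype=float)
    # cheap bounding-box prefilter, then exact containment in storage order
    v = mesh.element_vertices()
    pad = 1e-9 * (v.max(axis=(0, 1)) - v.min(axis=(0, 1))).max()
    cand = np.nonzero(
        ((v.min(axis=1) - pad) <= point).all(axis=1)
        & ((v.max(axis=1) + pad) >= point).all(axis=1)
    )[0]
    for e in cand:
        _, inside = local_coordinates(mesh, int(e), point)
        if inside:
            return int(e)
    return None


def locate(mesh: Mesh, index: CenterIndex, point):
    """Containing element of ``point``: nearest-center seed + edge-hopping.

    Falls back to :func:`linear_locate` when the walk gets stuck.  Returns
    ``None`` iff no element contains the point.
    """
    point = np.asarray(point, dtype=float)
    start = index.nearest(point)
    status, elem = edge_hop(mesh, start, point)
    if status is HopStatus.FOUND:
        return elem
    if status is HopStatus.OUTSIDE:
        # boundary face separated the point: outside for convex meshes, but
        # verify for non-convex ones
        near = linear_locate(mesh, point)
        return near
    return linear_locate(mesh, point)
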