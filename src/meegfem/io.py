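"""Readers and writers for the plain-text formats the toolbox consumes.

Formats: gmsh MSH ASCII v2.2 meshes (volume elements of type 4/tet or
5/hex, physical tag used as tissue label), conductivity ``.dat`` files
(one line per distinct label, sorted ascending; either a single scalar
for an isotropic tensor or six values ``xx yy zz xy xz yz``), dipole
files (6 columns: position, moment), electrode files (3 columns),
coil files (6 columns: position, measurement direction), source-space
files (6 columns: position, unit normal), and an ``.npz`` container with
a provenance header for transfer matrices.
"""

from __future__ import annotations

import json

import numpy as np

from .mesh import Dipole, Mesh, VolumeConductor

_MSH_TYPE_NNODES = {1: 2, 2: 3, 3: 4, 4: 4, 5: 8, 15: 1}


def read_gmsh(path) -> Mesh:
    """Read an ASCII MSH v2.2 file into a :class:`Mesh`.

    Only volume elements (type 4 tetrahedra or type 5 hexahedra) are kept;
    lower-dimensional elements are ignored.  The first (physical) tag is
    used as the tissue label.  1-based node indices are converted to
    0-based.  ``face_neighbors`` is not populated.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        i = lines.index("$MeshFormat")
    except ValueError:
        raise ValueError("missing $MeshFormat section") from None
    version = lines[i + 1].split()
    if not version or not version[0].startswith("2.2") or version[1] != "0":
        raise ValueError(f"unsupported MSH version/format: {lines[i + 1]!r}")
    try:
        i = lines.index("$Nodes")
    except ValueError:
        raise ValueError("missing $Nodes section") from None
    n_nodes = int(lines[i + 1])
    verts = np.empty((n_nodes, 3))
    id_map = {}
    for k in range(n_nodes):
        parts = lines[i + 2 + k].split()
        id_map[int(parts[0])] = k
        verts[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
    try:
        i = lines.index("$Elements")
    except ValueError:
        raise ValueError("missing $Elements section") from None
    n_el = int(lines[i + 1])
    conn, labels, kinds = [], [], set()
    for k in range(n_el):
        parts = lines[i + 2 + k].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        nodes = parts[3 + ntags:]
        if etype not in _MSH_TYPE_NNODES:
            raise ValueError(f"unsupported MSH element type {etype}")
        if etype not in (4, 5):
            continue
        kinds.add(etype)
        if len(kinds) > 1:
            raise ValueError("mixed element kinds (tetrahedra and hexahedra)")
        label = int(parts[3]) if ntags >= 1 else 0
        conn.append([id_map[int(n)] for n in nodes])
        labels.append(label)
    if not conn:
        raise ValueError("no volume elements (type 4 or 5) in file")
    kind = "tetrahedron" if kinds == {4} else "hexahedron"
    return Mesh(kind, verts, np.array(conn), np.array(labels))


def write_gmsh(path, mesh: Mesh) -> None:
    """Write a mesh as ASCII MSH v2.2 (round-trips with :func:`read_gmsh`)."""
    etype = 4 if mesh.element_kind == "tetrahedron" else 5
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, v in enumerate(mesh.vertices, start=1):
            fh.write(
                f"{i} {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n"
            )
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (conn, lab) in enumerate(zip(mesh.elements, mesh.labels), start=1):
            nodes = " ".join(str(int(c) + 1) for c in conn)
            fh.write(f"{i} {etype} 2 {int(lab)} {int(lab)} {nodes}\n")
        fh.write("$EndElements\n")


def read_conductivities(path, mesh: Mesh) -> VolumeConductor:
    """Read per-label conductivities and attach them to ``mesh``.

    Line ``k`` holds the conductivity of the k-th distinct label in
    ascending order: one positive scalar (isotropic) or six values
    ``xx yy zz xy xz yz`` forming a symmetric tensor.
    """
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#")[0].strip()
            if ln:
                rows.append([float(x) for x in ln.split()])
    labels = np.unique(mesh.labels)
    if len(rows) != len(labels):
        raise ValueError(
            f"conductivity file has {len(rows)} lines but mesh has "
            f"{len(labels)} distinct labels"
        )
    mapping = {}
    for lab, row in zip(labels, rows):
        if len(row) == 1:
            if row[0] <= 0:
                raise ValueError("non-positive conductivity")
            mapping[int(lab)] = row[0]
        elif len(row) == 6:
            xx, yy, zz, xy, xz, yz = row
            mapping[int(lab)] = np.array(
                [[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]]
            )
        else:
            raise ValueError("conductivity line must have 1 or 6 values")
    return VolumeConductor.from_label_values(mesh, mapping)


def write_conductivities(path, values) -> None:
    """Write per-label conductivities (scalars or 3x3 tensors, label-ascending)."""
    with open(path, "w") as fh:
        for val in values:
            v = np.asarray(val, dtype=float)
            if v.ndim == 0:
                fh.write(f"{float(v)!r}\n")
            else:
                fh.write(
                    " ".join(
                        repr(float(x))
                        for x in (v[0, 0], v[1, 1], v[2, 2], v[0, 1], v[0, 2], v[1, 2])
                    )
                    + "\n"
                )


def _read_columns(path, ncols):
    rows = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#")[0].strip()
            if not ln:
                continue
            parts = [float(x) for x in ln.split()]
            if len(parts) != ncols:
                raise ValueError(f"expected {ncols} columns, got {len(parts)}")
            rows.append(parts)
    return np.array(rows).reshape(-1, ncols)


def read_dipoles(path) -> list[Dipole]:
    """Read a dipole file: 6 whitespace-separated columns x y z qx qy qz."""
    data = _read_columns(path, 6)
    return [Dipole(row[:3], row[3:]) for row in data]


def write_dipoles(path, dipoles) -> None:
    with open(path, "w") as fh:
        for d in dipoles:
            fh.write(" ".join(repr(float(x)) for x in (*d.position, *d.moment)) + "\n")


def read_electrodes(path) -> np.ndarray:
    """Read electrode positions (3 columns per line)."""
    return _read_columns(path, 3)


def write_electrodes(path, positions) -> None:
    with open(path, "w") as fh:
        for p in np.asarray(positions, dtype=float):
            fh.write(" ".join(repr(float(x)) for x in p) + "\n")


def read_coils(path):
    """Read MEG coils (6 columns: position, direction) into a CoilSet."""
    from .meg import CoilSet

    data = _read_columns(path, 6)
    return CoilSet(data[:, :3], data[:, 3:])


def write_coils(path, coils) -> None:
    with open(path, "w") as fh:
        for p, d in zip(coils.positions, coils.directions):
            fh.write(" ".join(repr(float(x)) for x in (*p, *d)) + "\n")


def read_source_space(path):
    """Read a source space (6 columns: position, unit normal)."""
    from .scan import SourceSpace

    data = _read_columns(path, 6)
    return SourceSpace(data[:, :3], data[:, 3:])


def write_source_space(path, space) -> None:
    with open(path, "w") as fh:
        for p, n in zip(space.positions, space.normals):
            fh.write(" ".join(repr(float(x)) for x in (*p, *n)) + "\n")


def save_transfer(path, transfer) -> None:
    """Persist a transfer matrix with its provenance header as ``.npz``."""
    np.savez_compressed(
        path,
        matrix=transfer.matrix,
        provenance=np.frombuffer(
            json.dumps(transfer.provenance, sort_keys=True).encode(), dtype=np.uint8
        ),
    )


def load_transfer(path):
    from .eeg import TransferMatrix

    with np.load(path) as data:
        matrix = data["matrix"]
        prov = json.loads(bytes(data["provenance"].tobytes()).decode())
    return TransferMatrix(matrix, prov)
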