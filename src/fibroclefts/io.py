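"""CARP-style text mesh I/O and legacy-VTK export.

The on-disk dialect is the line-oriented text format used by cardiac
simulation tools:

``<base>.pts``
    Line 1: vertex count.  Then one ``x y z`` line per vertex (mm).
``<base>.elem``
    Line 1: element count.  Then ``Tr v0 v1 v2 tag`` (triangle) or
    ``Tt v0 v1 v2 v3 tag`` (tetrahedron) per line, 0-based indices.
``<base>.lon``
    One line per element with 3 numbers (fibre direction only) or 9 numbers
    (full fibre / sheet / sheet-normal triad).  No header line.

Counts and indices round-trip bit-exactly; coordinates round-trip to the
printed precision (%.6f).
"""

from __future__ import annotations

import os

import numpy as np

from .mesh import Mesh, MeshError

__all__ = ["read_mesh", "write_mesh", "write_vtk", "MeshFormatError"]

_PREFIX = {3: "Tr", 4: "Tt"}
_ARITY = {"Tr": 3, "Tt": 4}


class MeshFormatError(MeshError):
    """Malformed mesh file; the message names the offending file and line."""


def _read_count_header(lines, path):
    try:
        return int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise MeshFormatError(f"{path}:1: expected an integer count header")


def read_mesh(basename: str | os.PathLike) -> Mesh:
    """Read ``<basename>.pts`` / ``.elem`` (and ``.lon`` if present)."""
    base = os.fspath(basename)
    pts_path, elem_path, lon_path = (base + s for s in (".pts", ".elem", ".lon"))

    with open(pts_path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    n_pts = _read_count_header(lines, pts_path)
    if len(lines) - 1 != n_pts:
        raise MeshFormatError(
            f"{pts_path}:1: header says {n_pts} vertices, found {len(lines) - 1}"
        )
    vertices = np.empty((n_pts, 3))
    for i, ln in enumerate(lines[1:]):
        parts = ln.split()
        if len(parts) != 3:
            raise MeshFormatError(f"{pts_path}:{i + 2}: expected 3 coordinates")
        try:
            vertices[i] = [float(p) for p in parts]
        except ValueError:
            raise MeshFormatError(f"{pts_path}:{i + 2}: bad coordinate value")

    with open(elem_path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    n_elem = _read_count_header(lines, elem_path)
    if len(lines) - 1 != n_elem:
        raise MeshFormatError(
            f"{elem_path}:1: header says {n_elem} elements, found {len(lines) - 1}"
        )
    elements = None
    tags = np.empty(n_elem, dtype=np.int64)
    for i, ln in enumerate(lines[1:]):
        parts = ln.split()
        kind = parts[0]
        if kind not in _ARITY:
            raise MeshFormatError(
                f"{elem_path}:{i + 2}: unknown element type {kind!r}"
            )
        arity = _ARITY[kind]
        if len(parts) != arity + 2:
            raise MeshFormatError(
                f"{elem_path}:{i + 2}: expected {arity} indices and a tag"
            )
        if elements is None:
            elements = np.empty((n_elem, arity), dtype=np.int64)
        elif elements.shape[1] != arity:
            raise MeshFormatError(
                f"{elem_path}:{i + 2}: mixed element arities are unsupported"
            )
        try:
            elements[i] = [int(p) for p in parts[1 : 1 + arity]]
            tags[i] = int(parts[-1])
        except ValueError:
            raise MeshFormatError(f"{elem_path}:{i + 2}: bad index or tag")
    if elements is None:
        raise MeshFormatError(f"{elem_path}:1: no elements")

    orientation = None
    if os.path.exists(lon_path):
        with open(lon_path) as fh:
            lines = [ln for ln in (l.strip() for l in fh) if ln]
        if len(lines) != n_elem:
            raise MeshFormatError(
                f"{lon_path}:1: expected {n_elem} lines, found {len(lines)}"
            )
        orientation = np.empty((n_elem, 3, 3))
        for i, ln in enumerate(lines):
            vals = [float(p) for p in ln.split()]
            if len(vals) == 9:
                orientation[i] = np.asarray(vals).reshape(3, 3)
            elif len(vals) == 3:
                orientation[i] = _complete_triad(np.asarray(vals))
            else:
                raise MeshFormatError(
                    f"{lon_path}:{i + 1}: expected 3 or 9 numbers"
                )

    return Mesh(vertices, elements, tags, orientation)


def _complete_triad(fibre: np.ndarray) -> np.ndarray:
    """Build an orthonormal triad from a fibre direction alone.

    The sheet direction is chosen as the most stable perpendicular; the
    resulting triad is arbitrary up to rotation about the fibre.
    """
    f = fibre / np.linalg.norm(fibre)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(f @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    s = np.cross(ref, f)
    s /= np.linalg.norm(s)
    n = np.cross(f, s)
    return np.vstack([f, s, n])


def write_mesh(basename: str | os.PathLike, mesh: Mesh) -> None:
    """Write ``<basename>.pts`` / ``.elem`` (and ``.lon`` if triads exist)."""
    base = os.fspath(basename)
    with open(base + ".pts", "w") as fh:
        fh.write(f"{mesh.n_vertices}\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
    prefix = _PREFIX[mesh.elements.shape[1]]
    with open(base + ".elem", "w") as fh:
        fh.write(f"{mesh.n_elements}\n")
        for elem, tag in zip(mesh.elements, mesh.region_tag):
            idx = " ".join(str(int(v)) for v in elem)
            fh.write(f"{prefix} {idx} {int(tag)}\n")
    if mesh.orientation is not None:
        with open(base + ".lon", "w") as fh:
            for triad in mesh.orientation:
                fh.write(" ".join(f"{v:.6f}" for v in triad.ravel()) + "\n")


def write_vtk(path: str | os.PathLike, mesh: Mesh, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Export a mesh as a legacy-ASCII VTK unstructured grid.

    ``cell_data`` / ``point_data`` map scalar-field names to per-element /
    per-vertex arrays, written as ``SCALARS`` sections for visualization.
    """
    arity = mesh.elements.shape[1]
    vtk_type = 5 if arity == 3 else 10  # VTK_TRIANGLE / VTK_TETRA
    with open(os.fspath(path), "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfibroclefts mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {m * (arity + 1)}\n")
        for elem in mesh.elements:
            fh.write(f"{arity} " + " ".join(str(int(v)) for v in elem) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.writelines(f"{vtk_type}\n" for _ in range(m))
        cell_data = dict(cell_data or {})
        cell_data.setdefault("region_tag", mesh.region_tag)
        fh.write(f"CELL_DATA {m}\n")
        for name, values in cell_data.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            fh.writelines(f"{float(v):.6g}\n" for v in np.asarray(values))
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.writelines(f"{float(v):.6g}\n" for v in np.asarray(values))
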