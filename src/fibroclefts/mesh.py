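"""Simplex mesh container and adjacency indexing.

Meshes are triangles (2D, embedded in the z=0 plane) or tetrahedra (3D).
Vertex coordinates are in millimetres and always stored as (n, 3) arrays so
that geometric operations (face normals, orientation triads) are uniform
across dimensions.  Indexing is 0-based throughout; the on-disk dialects in
:mod:`fibroclefts.io` document any deviation.

A *face* of a simplex is a (d-1)-simplex: an edge of a triangle or a
triangular face of a tetrahedron.  Faces are identified by their sorted
vertex tuple (:func:`face_key`), which is independent of element winding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Mesh",
    "AdjacencyIndex",
    "MeshError",
    "NonManifoldError",
    "face_key",
    "element_faces",
    "build_adjacency",
]


class MeshError(ValueError):
    """Invalid mesh structure or geometry."""


class NonManifoldError(MeshError):
    """A face is shared by more than two elements."""


def face_key(vertices) -> tuple[int, ...]:
    """Canonical identity of a face: the sorted tuple of its vertex indices."""
    return tuple(sorted(int(v) for v in vertices))


def element_faces(element) -> list[tuple[int, ...]]:
    """All (d-1)-faces of a simplex, as canonical face keys.

    A triangle yields its 3 edges, a tetrahedron its 4 triangular faces.
    """
    element = [int(v) for v in element]
    k = len(element) - 1
    return [face_key(c) for c in itertools.combinations(element, k)]


@dataclass
class Mesh:
    """Simplex mesh with per-element region tags and orientation triads.

    Parameters
    ----------
    vertices
        (n, 3) float array of coordinates in mm.  2D meshes live in z = 0.
    elements
        (m, 3) or (m, 4) int array of vertex indices (triangles/tets).
    region_tag
        (m,) int array; 0 = normal myocardium, 1 = LGE (enhanced) region.
    orientation
        (m, 3, 3) float array; ``orientation[e]`` has rows fibre ``f``,
        sheet ``s`` and sheet-normal ``n``, an orthonormal triad.  May be
        ``None`` for meshes that never see an anisotropic solve.
    """

    vertices: np.ndarray
    elements: np.ndarray
    region_tag: np.ndarray = None
    orientation: np.ndarray = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] not in (2, 3):
            raise MeshError("vertices must be an (n, 2) or (n, 3) array")
        if self.vertices.shape[1] == 2:  # embed 2D coordinates in z = 0
            self.vertices = np.hstack(
                [self.vertices, np.zeros((len(self.vertices), 1))]
            )
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] not in (3, 4):
            raise MeshError("elements must be an (m, 3) or (m, 4) array")
        if self.region_tag is None:
            self.region_tag = np.zeros(len(self.elements), dtype=np.int64)
        else:
            self.region_tag = np.asarray(self.region_tag, dtype=np.int64)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)

    # -- basic queries ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def dim(self) -> int:
        """Topological dimension: 2 for triangles, 3 for tetrahedra."""
        return self.elements.shape[1] - 1

    def measures(self) -> np.ndarray:
        """Per-element area (2D) or signed volume (3D), mm^2 / mm^3."""
        x = self.vertices[self.elements]
        if self.dim == 2:
            a = x[:, 1] - x[:, 0]
            b = x[:, 2] - x[:, 0]
            return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
        a = x[:, 1] - x[:, 0]
        b = x[:, 2] - x[:, 0]
        c = x[:, 3] - x[:, 0]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def centroids(self) -> np.ndarray:
        return self.vertices[self.elements].mean(axis=1)

    def face_normal(self, face) -> np.ndarray:
        """Unit normal of a face.

        For a 3D triangular face this is the plane normal; for a 2D edge it
        is the in-plane perpendicular.  The sign is arbitrary (faces have no
        preferred orientation); callers must treat n and -n as equivalent.
        """
        pts = self.vertices[list(face)]
        if len(face) == 3:
            n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
        else:
            d = pts[1] - pts[0]
            n = np.array([-d[1], d[0], 0.0])
        norm = np.linalg.norm(n)
        if norm == 0:
            raise MeshError(f"degenerate face {tuple(face)}")
        return n / norm

    def validate(self, atol: float = 1e-8) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure.

        Verifies index bounds, non-degenerate simplices (positive area /
        volume) and, when present, orthonormality of the orientation triads.
        """
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= self.n_vertices
        ):
            raise MeshError("element vertex index out of range")
        meas = self.measures()
        if np.any(np.abs(meas) < 1e-14):
            bad = int(np.argmin(np.abs(meas)))
            raise MeshError(f"degenerate element {bad}")
        if self.dim == 3 and np.any(meas < 0):
            raise MeshError("negatively oriented tetrahedra present")
        if len(self.region_tag) != self.n_elements:
            raise MeshError("region_tag length mismatch")
        if self.orientation is not None:
            if self.orientation.shape != (self.n_elements, 3, 3):
                raise MeshError("orientation must be (m, 3, 3)")
            gram = np.einsum("eij,ekj->eik", self.orientation, self.orientation)
            if not np.allclose(gram, np.eye(3), atol=atol):
                raise MeshError("orientation triads are not orthonormal")

    def copy(self) -> "Mesh":
        return Mesh(
            self.vertices.copy(),
            self.elements.copy(),
            self.region_tag.copy(),
            None if self.orientation is None else self.orientation.copy(),
        )


@dataclass
class AdjacencyIndex:
    """Face-to-element and vertex-to-element (star) lookup tables.

    ``face_to_elements`` maps each canonical face key to the 1 (boundary) or
    2 (interior) elements containing it.  ``vertex_to_elements`` maps each
    vertex to its star, the set of elements incident to it.
    """

    face_to_elements: dict = field(default_factory=dict)
    vertex_to_elements: dict = field(default_factory=dict)

    def interior_faces(self):
        """Iterate over face keys shared by exactly two elements."""
        return (f for f, els in self.face_to_elements.items() if len(els) == 2)

    def is_interior(self, face) -> bool:
        return len(self.face_to_elements.get(face_key(face), ())) == 2

    def star(self, vertex: int) -> list[int]:
        return self.vertex_to_elements.get(int(vertex), [])


def build_adjacency(mesh: Mesh) -> AdjacencyIndex:
    """Index faces and vertex stars of a mesh.

    Raises
    ------
    NonManifoldError
        If any face is contained in more than two elements.
    """
    face_to_elements: dict[tuple, list[int]] = {}
    vertex_to_elements: dict[int, list[int]] = {}
    for e, elem in enumerate(mesh.elements):
        for v in elem:
            vertex_to_elements.setdefault(int(v), []).append(e)
        for fk in element_faces(elem):
            owners = face_to_elements.setdefault(fk, [])
            owners.append(e)
            if len(owners) > 2:
                raise NonManifoldError(
                    f"face {fk} is shared by more than two elements"
                )
    return AdjacencyIndex(face_to_elements, vertex_to_elements)
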