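"""Mesh generators: 2D test grids, 3D slabs and synthetic image fixtures.

The patient geometry behind an LGE-informed model is not distributable, so
everything here builds synthetic substrates: structured triangular grids
(the 2D conduction-block test case), structured tetrahedral slabs with
orientation triads, small worked-example stars for the splitting algorithm,
and a smooth radially decaying intensity field standing in for an LGE-CMR
enhancement zone.
"""

from __future__ import annotations

import numpy as np

from .fibrosis import FibrosisNetwork, IntensityField
from .mesh import Mesh, face_key

__all__ = [
    "make_grid_2d",
    "make_slab_3d",
    "make_cross_testcase",
    "make_fan_2d",
    "make_tet_fan_3d",
    "synthetic_lge_fixture",
]

_DEFAULT_TRIAD = np.array(
    [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)
# in 2D the sheet normal must lie in-plane (sheets stack across the fibres),
# otherwise every in-plane edge is orthogonal to it and no face can ever be
# sampled as fibrotic
_GRID_TRIAD = np.array(
    [[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]]
)


def make_grid_2d(n_boxes: int, box_edge: float = 0.25, diagonal: str = "lr") -> Mesh:
    """Structured triangular grid of ``n_boxes`` x ``n_boxes`` square boxes.

    Each box is divided into two triangles by a diagonal running from the
    lower-left to the upper-right corner (``diagonal="lr"``, the default) or
    from the lower-right to the upper-left (``"rl"``).  ``box_edge`` is the
    box side length in mm, so 38 boxes at 0.25 mm give the 9.5 mm x 9.5 mm
    conduction test domain.  Fibres are along +x with the sheet normal
    in-plane along +y (sheets stack across the fibres).
    """
    if n_boxes < 1:
        raise ValueError("n_boxes must be >= 1")
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    if diagonal not in ("lr", "rl"):
        raise ValueError("diagonal must be 'lr' or 'rl'")
    n = n_boxes
    xs = np.arange(n + 1) * box_edge
    gx, gy = np.meshgrid(xs, xs, indexing="xy")
    vertices = np.column_stack([gx.ravel(), gy.ravel(), np.zeros((n + 1) ** 2)])

    def vid(i, j):  # column i, row j
        return j * (n + 1) + i

    elements = []
    for j in range(n):
        for i in range(n):
            v00, v10 = vid(i, j), vid(i + 1, j)
            v01, v11 = vid(i, j + 1), vid(i + 1, j + 1)
            if diagonal == "lr":
                elements.append((v00, v10, v11))
                elements.append((v00, v11, v01))
            else:
                elements.append((v00, v10, v01))
                elements.append((v10, v11, v01))
    orientation = np.broadcast_to(_GRID_TRIAD, (len(elements), 3, 3)).copy()
    return Mesh(vertices, np.asarray(elements), orientation=orientation)


def _constant_orientation(centroids: np.ndarray) -> np.ndarray:
    return np.broadcast_to(_DEFAULT_TRIAD, (len(centroids), 3, 3)).copy()


def make_slab_3d(dims, target_edge: float, orientation_rule=None) -> Mesh:
    """Structured tetrahedral slab of extents ``dims`` (mm).

    The box is divided into a lattice of hexahedral cells of edge close to
    ``target_edge`` and each cell into 5 tetrahedra; the corner-tet parity
    alternates between neighbouring cells so that shared faces match.
    ``orientation_rule`` maps element centroids (m, 3) to triads (m, 3, 3);
    the default is fibre +x, sheet +y, sheet-normal +z everywhere.
    """
    dims = np.asarray(dims, dtype=float)
    if dims.shape != (3,) or np.any(dims <= 0):
        raise ValueError("dims must be three positive lengths")
    if not 0 < target_edge <= dims.min():
        raise ValueError("target_edge must be in (0, min(dims)]")
    counts = np.maximum(1, np.round(dims / target_edge).astype(int))
    nx, ny, nz = (int(c) for c in counts)
    hx, hy, hz = dims / counts

    def vid(i, j, k):
        return (k * (ny + 1) + j) * (nx + 1) + i

    ii, jj, kk = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    vertices = np.empty(((nx + 1) * (ny + 1) * (nz + 1), 3))
    flat = vid(ii, jj, kk).ravel()
    vertices[flat, 0] = (ii * hx).ravel()
    vertices[flat, 1] = (jj * hy).ravel()
    vertices[flat, 2] = (kk * hz).ravel()

    # 5-tet decomposition: the central tet sits on one parity class of cell
    # corners; flipping the class in neighbouring cells makes faces match.
    even_scheme = [
        ((1, 0, 0), (0, 0, 0), (1, 1, 0), (1, 0, 1)),
        ((0, 1, 0), (0, 0, 0), (1, 1, 0), (0, 1, 1)),
        ((0, 0, 1), (0, 0, 0), (1, 0, 1), (0, 1, 1)),
        ((1, 1, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
        ((0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)),
    ]
    odd_scheme = [
        ((0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)),
        ((1, 1, 0), (1, 0, 0), (0, 1, 0), (1, 1, 1)),
        ((1, 0, 1), (1, 0, 0), (0, 0, 1), (1, 1, 1)),
        ((0, 1, 1), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
        ((1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)),
    ]
    elements = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                scheme = even_scheme if (i + j + k) % 2 == 0 else odd_scheme
                for tet in scheme:
                    elements.append(
                        tuple(vid(i + d[0], j + d[1], k + d[2]) for d in tet)
                    )
    elements = np.asarray(elements, dtype=np.int64)
    mesh = Mesh(vertices, elements)
    vols = mesh.measures()
    flip = vols < 0  # normalize winding to positive volume
    elements[flip] = elements[flip][:, [0, 1, 3, 2]]
    mesh = Mesh(vertices, elements)
    rule = orientation_rule or _constant_orientation
    mesh.orientation = np.asarray(rule(mesh.centroids()), dtype=float)
    return mesh


def make_cross_testcase(
    topology: str = "tight",
    n_boxes: int = 38,
    box_edge: float = 0.25,
    n_crosses: int = 10,
    row: int | None = None,
):
    """The 2D conduction-block test case: a grid with a row of split crosses.

    Builds the ``n_boxes`` x ``n_boxes`` triangular grid and designates a
    horizontal row of ``n_crosses`` plus-shaped crosses of split edges (one
    edge per arm).  The crosses are evenly spaced with uniform gaps chosen so
    the row spans the full domain width (for the default 38 boxes and 10
    crosses: 2-box gaps and the outermost arm tips on the lateral
    boundaries), so a wavefront can only pass through the inter-cross gaps.

    Both topologies share the identical split-edge set; ``topology`` only
    records the intended node-assignment mode ("tight" = full local
    connectivity analysis, "leaky" = diagonally merged groups at each cross
    centre) and the expected number of element groups per cross centre.

    Returns ``(mesh, network, expected)`` where ``expected`` holds the
    cross-centre vertex ids, the expected group count per centre, the row
    height (mm) and the assignment mode to pass to the splitter.
    """
    if topology not in ("tight", "leaky"):
        raise ValueError("topology must be 'tight' or 'leaky'")
    mesh = make_grid_2d(n_boxes, box_edge)
    row = n_boxes // 2 if row is None else row
    # centres evenly spread so arms + gaps tile the full width
    span = n_boxes - 2  # first centre at column 1, last at n_boxes - 1
    centres_x = [1 + round(span * k / (n_crosses - 1)) for k in range(n_crosses)]

    def vid(i, j):
        return j * (n_boxes + 1) + i

    faces = set()
    centre_vertices = []
    for cx in centres_x:
        c = vid(cx, row)
        centre_vertices.append(c)
        faces.add(face_key((vid(cx - 1, row), c)))
        faces.add(face_key((c, vid(cx + 1, row))))
        faces.add(face_key((vid(cx, row - 1), c)))
        faces.add(face_key((c, vid(cx, row + 1))))
    network = FibrosisNetwork(faces, seed=None, rho_max=0.0)
    expected = {
        "cross_centres": centre_vertices,
        "components_per_centre": 4 if topology == "tight" else 2,
        "assignment": topology,
        "row_y": row * box_edge,
        "box_edge": box_edge,
    }
    return mesh, network, expected


def make_fan_2d(n_triangles: int = 5) -> Mesh:
    """Closed fan of triangles around a central vertex.

    Ring vertices 0..n-1 sit on the unit circle; the hub is the last vertex
    (index n).  Triangle ``e_i`` is (hub, ring_i, ring_{i+1}), so the edge
    shared by ``e_i`` and ``e_{i+1}`` is (hub, ring_{i+1}).  With n = 5 this
    is the classic worked example for the local connectivity analysis:
    splitting the edges between e2-e3, e3-e4 and e1-e5 leaves the components
    {e1, e2}, {e3}, {e4, e5} around the hub.
    """
    if n_triangles < 3:
        raise ValueError("need at least 3 triangles for a closed fan")
    n = n_triangles
    ang = 2 * np.pi * np.arange(n) / n
    ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
    vertices = np.vstack([ring, [[0.0, 0.0, 0.0]]])
    hub = n
    elements = [(hub, i, (i + 1) % n) for i in range(n)]
    return Mesh(vertices, np.asarray(elements))


def make_tet_fan_3d() -> Mesh:
    """Fan of 4 tetrahedra around a shared interior edge.

    The axis edge runs between vertices 3 (base, origin) and 5 (apex); the
    ring vertices 0, 1, 2, 4 sit at 90-degree intervals around it.  Elements
    e1..e4 (indices 0..3) wrap around the axis, so e1 and e4 share face
    (3, 4, 5) while the face (1, 3, 5) between e2 and e3 is coplanar with
    it.  This reproduces the 3D fallback-disconnection worked example: with
    face (3, 4, 5) split, e1 and e4 stay connected through e2 and e3 until
    the coplanar face (1, 3, 5) is removed from the local connectivity,
    leaving the groups {e1, e2} and {e3, e4}.
    """
    vertices = np.array(
        [
            [1.0, 0.0, 0.0],   # 0: ring, angle 0
            [0.0, 1.0, 0.0],   # 1: ring, angle 90
            [-1.0, 0.0, 0.0],  # 2: ring, angle 180
            [0.0, 0.0, 0.0],   # 3: axis base
            [0.0, -1.0, 0.0],  # 4: ring, angle 270
            [0.0, 0.0, 1.0],   # 5: axis apex
        ]
    )
    elements = np.array(
        [
            (5, 3, 4, 0),  # e1: between ring 4 and ring 0
            (5, 3, 0, 1),  # e2: between ring 0 and ring 1
            (5, 3, 1, 2),  # e3: between ring 1 and ring 2
            (5, 3, 2, 4),  # e4: between ring 2 and ring 4
        ]
    )
    mesh = Mesh(vertices, elements)
    vols = mesh.measures()
    elements[vols < 0] = elements[vols < 0][:, [0, 1, 3, 2]]
    return Mesh(vertices, elements)


def synthetic_lge_fixture(
    mesh: Mesh,
    centre,
    radius: float,
    seed: int = 0,
    i_ref: float = 1.0,
    i_max: float = 3.0,
    noise: float = 0.0,
) -> IntensityField:
    """Smooth radially decaying intensity emulating an LGE enhancement zone.

    The per-element intensity is ``i_ref + (i_max - i_ref) * f(r)`` with
    ``f(r) = max(0, 1 - (r/radius)^2)`` and r the centroid distance to
    ``centre`` — maximal enhancement at the centre, decaying to the
    reference level at the radius and beyond (so the normalized intensity
    outside the radius is exactly 0).  Optional multiplicative jitter of
    relative amplitude ``noise`` (seeded, clipped to keep f in [0, 1])
    roughens the profile; the field is deterministic given the seed.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centre = np.asarray(centre, dtype=float)
    if centre.shape == (2,):
        centre = np.append(centre, 0.0)
    r = np.linalg.norm(mesh.centroids() - centre, axis=1)
    f = np.clip(1.0 - (r / radius) ** 2, 0.0, 1.0)
    if noise > 0:
        rng = np.random.default_rng(seed)
        f = np.clip(f * (1.0 + noise * (rng.random(len(f)) - 0.5)), 0.0, 1.0)
    return IntensityField(i_ref + (i_max - i_ref) * f, i_ref, i_max)
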