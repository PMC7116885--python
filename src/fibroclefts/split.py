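"""Discrete-finite-element splitting of fibrotic faces.

Clefts of interstitial fibrosis are represented as infinitesimal no-flux
discontinuities: every vertex lying on a fibrotic (split) face is analysed
and, where the local element connectivity falls apart into several groups,
duplicated so that each group references its own copy of the vertex.  The
duplicated nodes coincide geometrically with the originals, so the mesh
geometry is unchanged while current can no longer flow across split faces
("tight" topology).

The local analysis at a vertex builds a graph whose nodes are the elements
of the vertex star; two elements are linked when they share a face (edge in
2D) containing the vertex that is *not* split.  The connected components of
this graph determine the number of vertex copies and their assignment.

When a split face fails to disconnect its two neighbouring elements (an
unbranched cleft end), the local connectivity is additionally cut along the
geometric continuation of the cleft: in 2D the edge closest to 180 degrees
from the split edge, in 3D the candidate faces most parallel to the split
face (largest |dot| of unit normals), removed one by one until the two
elements separate.  These fallback cuts modify the local connectivity only;
they are never added to the physical no-flux set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .fibrosis import FibrosisNetwork
from .mesh import Mesh, MeshError, build_adjacency, face_key

__all__ = [
    "LocalElementGraph",
    "SplitResult",
    "TightnessReport",
    "TopologyError",
    "local_element_graph",
    "fallback_disconnect",
    "split_at_vertex",
    "split_mesh",
    "remove_isolated_components",
    "audit_tightness",
]


class TopologyError(MeshError):
    """The local connectivity could not be disconnected (degenerate star)."""


@dataclass
class LocalElementGraph:
    """Element-connectivity graph of one vertex star.

    ``graph`` holds the element ids of the star as nodes, linked when two
    elements share an unsplit face containing the vertex.  ``link_face``
    records, for every potential link (split or not), the shared face in
    *current* vertex indices; ``split_pairs`` lists the element pairs whose
    shared face is in the fibrosis network, keyed by the original face key.
    """

    vertex: int
    graph: nx.Graph
    link_face: dict = field(default_factory=dict)
    split_pairs: list = field(default_factory=list)

    def components(self) -> list[tuple[int, ...]]:
        """Connected components as element-id tuples, ordered by their
        lowest element index (component 0 keeps the original vertex)."""
        comps = [tuple(sorted(c)) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: c[0])

    def same_component(self, p: int, q: int) -> bool:
        return nx.has_path(self.graph, p, q)


def _build_local_graph(elements, coords, star, vertex, net_at_v, orig_of):
    """Local element graph over ``star`` at ``vertex`` from current arrays.

    ``net_at_v`` maps each network face containing the vertex to the two
    elements adjacent to it in the *original* mesh; those element pairs are
    the disconnection targets even when earlier vertex splits have already
    removed the shared face from the current connectivity.
    """
    shared: dict[tuple, list[int]] = {}
    dim = elements.shape[1] - 1
    for e in star:
        elem = elements[e]
        others = [int(x) for x in elem if x != vertex]
        if dim == 2:
            faces = [tuple(sorted((vertex, o))) for o in others]
        else:
            faces = [
                tuple(sorted((vertex, others[0], others[1]))),
                tuple(sorted((vertex, others[0], others[2]))),
                tuple(sorted((vertex, others[1], others[2]))),
            ]
        for f in faces:
            shared.setdefault(f, []).append(e)
    g = nx.Graph()
    g.add_nodes_from(star)
    lgraph = LocalElementGraph(vertex, g)
    for f, els in shared.items():
        if len(els) != 2:
            continue
        p, q = els
        okey = face_key(orig_of[list(f)])
        lgraph.link_face[frozenset((p, q))] = f
        if okey not in net_at_v:
            g.add_edge(p, q)
    star_set = set(star)
    for fk in sorted(net_at_v):
        p, q = net_at_v[fk]
        if p in star_set and q in star_set:
            lgraph.split_pairs.append((p, q, fk))
    return lgraph


def local_element_graph(
    mesh: Mesh, vertex: int, network: FibrosisNetwork, adjacency=None
) -> LocalElementGraph:
    """Local connectivity analysis at one vertex of an (unsplit) mesh.

    If no network face touches the star the graph is simply connected and
    the caller can skip the vertex.
    """
    adjacency = adjacency or build_adjacency(mesh)
    vertex = int(vertex)
    star = sorted(adjacency.star(vertex))
    orig_of = np.arange(mesh.n_vertices)
    net_at_v = {}
    for fk in network.faces:
        fk = face_key(fk)
        if vertex in fk:
            owners = adjacency.face_to_elements.get(fk, ())
            if len(owners) == 2:
                net_at_v[fk] = tuple(owners)
    return _build_local_graph(mesh.elements, mesh.vertices, star, vertex,
                              net_at_v, orig_of)


def _face_normal(coords, face):
    pts = coords[list(face)]
    if len(face) == 3:
        n = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    else:
        d = pts[1] - pts[0]
        n = np.array([-d[1], d[0], 0.0])
    nrm = np.linalg.norm(n)
    if nrm == 0:
        raise MeshError(f"degenerate face {tuple(face)}")
    return n / nrm


def fallback_disconnect(
    lgraph: LocalElementGraph, face, coords, orig_of=None
) -> LocalElementGraph:
    """Cut the local connectivity so that the elements of ``face`` separate.

    ``face`` is the split face (current vertex indices) whose two adjacent
    elements are still in one component.  In 2D the single star edge whose
    angle to the split edge is closest to 180 degrees is removed; in 3D
    candidate faces are removed in descending order of |dot| between their
    unit normal and the split-face normal — the geometric continuation of
    the cleavage plane — until the two elements separate.  Removals apply to
    the local graph only.  Already-disconnected pairs return unchanged.

    Raises
    ------
    TopologyError
        If every candidate is removed without disconnecting the pair.
    """
    face = tuple(sorted(int(v) for v in face))
    hit = [sp for sp in lgraph.split_pairs if sp[2] == face]
    if not hit:
        raise ValueError(f"face {face} is not a split face at vertex {lgraph.vertex}")
    p, q, _ = hit[0]
    if not lgraph.same_component(p, q):
        return lgraph
    v = lgraph.vertex
    orig_of = (
        np.arange(len(coords)) if orig_of is None else np.asarray(orig_of)
    )
    if len(face) == 2:  # 2D: remove the most collinear opposite edge
        (w,) = (x for x in face if x != v)
        d0 = coords[w] - coords[v]
        d0 = d0 / np.linalg.norm(d0)
        best, best_cos = None, np.inf
        for pair, f in sorted(
            lgraph.link_face.items(), key=lambda kv: tuple(orig_of[list(kv[1])])
        ):
            if not lgraph.graph.has_edge(*pair):
                continue
            (u,) = (x for x in f if x != v)
            d = coords[u] - coords[v]
            c = float(d0 @ d / np.linalg.norm(d))
            if c < best_cos - 1e-12:
                best, best_cos = pair, c
        if best is None:
            raise TopologyError(f"no candidate edge at vertex {v}")
        lgraph.graph.remove_edge(*best)
        if lgraph.same_component(p, q):
            raise TopologyError(
                f"fallback edge removal did not disconnect elements at vertex {v}"
            )
        return lgraph
    # 3D: peel off faces most parallel to the split face
    n0 = _face_normal(coords, face)
    candidates = []
    for pair, f in lgraph.link_face.items():
        if not lgraph.graph.has_edge(*pair):
            continue
        score = abs(float(_face_normal(coords, f) @ n0))
        candidates.append((-score, tuple(orig_of[list(f)]), pair))
    for _, _, pair in sorted(candidates):
        lgraph.graph.remove_edge(*pair)
        if not lgraph.same_component(p, q):
            return lgraph
    raise TopologyError(
        f"exhausted candidate faces without disconnecting vertex {v}"
    )


def _merge_diagonal(components, elements, coords, vertex):
    """Leaky assignment: merge diagonally opposite groups at a 4-way vertex.

    Components are ordered by the angle of their centroid direction around
    the vertex and opposite pairs (i, i+2) are merged, emulating naive
    per-edge node doubling that leaves diagonal element groups connected.
    """
    origin = coords[vertex]
    angles = []
    for comp in components:
        cen = coords[elements[list(comp)].ravel()].mean(axis=0) - origin
        angles.append(np.arctan2(cen[1], cen[0]))
    order = np.argsort(angles)
    merged = []
    half = len(components) // 2
    for i in range(half):
        a = components[order[i]]
        b = components[order[i + half]]
        merged.append(tuple(sorted(a + b)))
    return sorted(merged, key=lambda c: c[0])


def split_at_vertex(mesh: Mesh, vertex: int, components) -> tuple[Mesh, dict]:
    """Duplicate ``vertex`` so each element group gets its own copy.

    ``components`` must partition the vertex star.  The group containing
    the lowest element index keeps the original vertex; every further group
    receives a fresh vertex with identical coordinates.  Returns the new
    mesh and a map ``new_vertex -> (original_vertex, component_id)``.
    """
    components = sorted((tuple(sorted(c)) for c in components), key=lambda c: c[0])
    if any(len(c) == 0 for c in components):
        raise ValueError("empty component in partition")
    new_mesh = mesh.copy()
    dup_map: dict[int, tuple[int, int]] = {}
    verts = [new_mesh.vertices]
    for cid, comp in enumerate(components[1:], start=1):
        new_id = len(mesh.vertices) + len(dup_map)
        verts.append(mesh.vertices[int(vertex)][None, :])
        dup_map[new_id] = (int(vertex), cid)
        for e in comp:
            row = new_mesh.elements[e]
            row[row == vertex] = new_id
    new_mesh.vertices = np.vstack(verts)
    return new_mesh, dup_map


@dataclass
class SplitResult:
    """Outcome of splitting a mesh along a fibrosis network.

    ``duplication_map`` maps each appended vertex to ``(original_vertex,
    component_id)``; ``vertex_components`` maps each analysed original
    vertex to its element groups with the vertex copy each group was
    assigned; ``orig_of`` maps every vertex of the split mesh back to its
    original index (identity for non-duplicated vertices).
    """

    mesh: Mesh
    duplication_map: dict = field(default_factory=dict)
    vertex_components: dict = field(default_factory=dict)
    removed_elements: np.ndarray = field(default_factory=lambda: np.array([], int))
    orig_of: np.ndarray = None
    fallback_vertices: set = field(default_factory=set)

    @property
    def n_duplicates(self) -> int:
        return len(self.duplication_map)


def _effective_network(mesh: Mesh, network: FibrosisNetwork):
    """Interior network faces; boundary clefts are warned about and ignored."""
    adjacency = build_adjacency(mesh)
    interior, skipped = set(), []
    for fk in network.faces:
        owners = adjacency.face_to_elements.get(face_key(fk), ())
        if len(owners) == 2:
            interior.add(face_key(fk))
        else:
            skipped.append(face_key(fk))
    if skipped:
        warnings.warn(
            f"ignoring {len(skipped)} network face(s) on the mesh boundary "
            "(a surface cleft has no interior to disconnect)"
        )
    return interior, adjacency


def split_mesh(
    mesh: Mesh, network: FibrosisNetwork, assignment: str = "tight"
) -> SplitResult:
    """Split a mesh along every interior face of a fibrosis network.

    Visits every vertex lying on at least one network face in ascending
    index order, performs the local connectivity analysis (with fallback
    disconnection where a cleft end does not separate its neighbours), and
    duplicates the vertex per element group.  ``assignment="leaky"`` applies
    the degraded diagonal-merge assignment at 4-group vertices instead — the
    same split-face set, but a topology that leaks current diagonally.

    After splitting, the two elements adjacent to any network face
    reference disjoint vertex sets on that face; geometry is unchanged.
    """
    if assignment not in ("tight", "leaky"):
        raise ValueError("assignment must be 'tight' or 'leaky'")
    interior, adjacency = _effective_network(mesh, network)
    net_adj = {fk: tuple(adjacency.face_to_elements[fk]) for fk in interior}
    faces_at_vertex: dict[int, list] = {}
    for fk in interior:
        for v in fk:
            faces_at_vertex.setdefault(v, []).append(fk)
    elements = mesh.elements.copy()
    coords = [mesh.vertices]
    orig_of = list(range(mesh.n_vertices))
    v2e = {v: set(els) for v, els in adjacency.vertex_to_elements.items()}
    result = SplitResult(mesh=None)

    visit = sorted(faces_at_vertex)
    n_orig = mesh.n_vertices
    n_total = n_orig
    all_coords = mesh.vertices
    for v in visit:
        star = sorted(v2e.get(v, ()))
        if not star:
            continue
        orig_arr = np.asarray(orig_of)
        net_at_v = {fk: net_adj[fk] for fk in faces_at_vertex[v]}
        lgraph = _build_local_graph(elements, all_coords, star, v, net_at_v,
                                    orig_arr)
        for p, q, fk in lgraph.split_pairs:
            if lgraph.same_component(p, q):
                fallback_disconnect(lgraph, fk, all_coords, orig_arr)
                result.fallback_vertices.add(v)
        components = lgraph.components()
        if len(components) == 1:
            continue
        if assignment == "leaky" and len(components) == 4:
            components = _merge_diagonal(components, elements, all_coords, v)
        assigned = [(components[0], v)]
        for cid, comp in enumerate(components[1:], start=1):
            new_id = n_total
            n_total += 1
            coords.append(mesh.vertices[v][None, :])
            orig_of.append(v)
            result.duplication_map[new_id] = (v, cid)
            for e in comp:
                row = elements[e]
                row[row == v] = new_id
                v2e[v].discard(e)
                v2e.setdefault(new_id, set()).add(e)
            assigned.append((comp, new_id))
        result.vertex_components[v] = assigned
        if n_total > n_orig:
            all_coords = np.vstack(coords)
    result.orig_of = np.asarray(orig_of)
    result.mesh = Mesh(
        np.vstack(coords),
        elements,
        mesh.region_tag.copy(),
        None if mesh.orientation is None else mesh.orientation.copy(),
    )
    return result


def remove_isolated_components(split: SplitResult) -> SplitResult:
    """Keep only the largest electrically connected component.

    A closed split surface can fully enclose elements; they can never be
    activated and are pruned (together with vertices no longer referenced).
    Electrical coupling in the finite-element discretization flows through
    shared *nodes*, so connectivity is vertex-sharing (elements that share
    any vertex are coupled, even across an unshared face at a cleft end).
    Ties for the largest component are broken deterministically towards the
    component containing the lowest element index, with a warning.
    """
    mesh = split.mesh
    adjacency = build_adjacency(mesh)
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_elements))
    for els in adjacency.vertex_to_elements.values():
        for e in els[1:]:  # chain the star: same component, fewer edges
            g.add_edge(els[0], e)
    comps = [tuple(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    if len(comps) > 1 and len(comps[0]) == len(comps[1]):
        warnings.warn(
            "tie for largest connected component; keeping the one with the "
            "lowest element index"
        )
    keep = np.asarray(comps[0])
    removed = np.setdiff1d(np.arange(mesh.n_elements), keep)
    if removed.size == 0:
        return SplitResult(
            mesh,
            dict(split.duplication_map),
            dict(split.vertex_components),
            removed,
            split.orig_of,
            set(split.fallback_vertices),
        )
    new_elements = mesh.elements[keep]
    used = np.unique(new_elements)
    vmap = -np.ones(mesh.n_vertices, dtype=np.int64)
    vmap[used] = np.arange(len(used))
    new_mesh = Mesh(
        mesh.vertices[used],
        vmap[new_elements],
        mesh.region_tag[keep],
        None if mesh.orientation is None else mesh.orientation[keep],
    )
    emap = -np.ones(mesh.n_elements, dtype=np.int64)
    emap[keep] = np.arange(len(keep))
    dup_map = {
        int(vmap[nv]): (ov, cid)
        for nv, (ov, cid) in split.duplication_map.items()
        if vmap[nv] >= 0
    }
    vertex_components = {}
    for v, groups in split.vertex_components.items():
        new_groups = []
        for comp, vid in groups:
            comp = tuple(int(emap[e]) for e in comp if emap[e] >= 0)
            if comp and vmap[vid] >= 0:
                new_groups.append((comp, int(vmap[vid])))
        if new_groups:
            vertex_components[v] = new_groups
    return SplitResult(
        new_mesh,
        dup_map,
        vertex_components,
        removed,
        split.orig_of[used],
        set(split.fallback_vertices),
    )


@dataclass
class TightnessReport:
    """Result of auditing a split mesh for current leaks."""

    passed: bool
    face_failures: list = field(default_factory=list)
    vertex_failures: list = field(default_factory=list)


def audit_tightness(split: SplitResult, network: FibrosisNetwork) -> TightnessReport:
    """Verify that a split mesh cannot leak current across the network.

    Two order-independent conditions are checked against the original
    connectivity reconstructed through ``orig_of``:

    1. the two elements originally adjacent across every network face share
       no vertex of the split mesh (the cleft is a genuine discontinuity);
    2. at every split vertex, element groups that the network faces
       disconnect in the original vertex star (connected components of the
       star graph with network-face links removed) reference disjoint sets
       of copies of that vertex — two disconnected groups sharing a node
       would let current leak through that node.

    Fallback cuts refine groups beyond this reference partition (extra
    duplication at cleft ends), which is conservative and passes.  A leaky
    (diagonally merged) assignment passes (1) but fails (2) at its merged
    vertices.  Failures are enumerated in the report, not raised.
    """
    mesh = split.mesh
    orig_of = split.orig_of
    orig_elements = orig_of[mesh.elements]
    face_to_elements: dict[tuple, list[int]] = {}
    v2e: dict[int, set] = {}
    for e, elem in enumerate(orig_elements):
        for v in elem:
            v2e.setdefault(int(v), set()).add(e)
        for c in itertools.combinations(sorted(int(x) for x in elem), mesh.dim):
            face_to_elements.setdefault(c, []).append(e)

    report = TightnessReport(True)
    interior = {
        face_key(fk)
        for fk in network.faces
        if len(face_to_elements.get(face_key(fk), ())) == 2
    }
    for fk in sorted(interior):
        e1, e2 = face_to_elements[fk]
        shared = set(mesh.elements[e1]) & set(mesh.elements[e2])
        if shared:
            report.face_failures.append(
                {"face": fk, "shared_vertices": sorted(int(s) for s in shared)}
            )
    identity = np.arange(mesh.n_vertices)
    for v in sorted({v for fk in interior for v in fk}):
        star = sorted(v2e.get(v, ()))
        if len(star) < 2:
            continue
        net_at_v = {fk: tuple(face_to_elements[fk])
                    for fk in interior if v in fk}
        lgraph = _build_local_graph(
            orig_elements, mesh.vertices, star, v, net_at_v, identity
        )
        comps = lgraph.components()
        if len(comps) < 2:
            continue
        copies = [
            {int(x) for e in comp for x in mesh.elements[e] if orig_of[x] == v}
            for comp in comps
        ]
        for a in range(len(comps)):
            for b in range(a + 1, len(comps)):
                leak = copies[a] & copies[b]
                if leak:
                    report.vertex_failures.append(
                        {"vertex": v, "groups": (list(comps[a]), list(comps[b])),
                         "shared_copies": sorted(leak)}
                    )
    report.passed = not report.face_failures and not report.vertex_failures
    return report
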