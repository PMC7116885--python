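import warnings

import numpy as np
import pytest
from helpers import star_components

from fibroclefts import (
    FibrosisNetwork,
    audit_tightness,
    local_element_graph,
    make_grid_2d,
    make_slab_3d,
    probability_map,
    remove_isolated_components,
    sample_network,
    split_at_vertex,
    split_mesh,
)
from fibroclefts.split import fallback_disconnect


def test_fan_local_components_match_oracle(fan5, fan_network):
    lgraph = local_element_graph(fan5, 5, fan_network)
    comps = lgraph.components()
    assert comps == [(0, 1), (2,), (3, 4)]
    assert comps == star_components(fan5, fan_network, 5)


def test_fan_untouched_star_is_single_component(fan5):
    lgraph = local_element_graph(fan5, 5, FibrosisNetwork(set()))
    assert len(lgraph.components()) == 1


def test_fan_fully_split_star_gives_singletons(fan5):
    network = FibrosisNetwork({(i, 5) for i in range(5)})
    lgraph = local_element_graph(fan5, 5, network)
    assert len(lgraph.components()) == 5


def test_split_at_vertex_adds_coincident_copies(fan5, fan_network):
    comps = local_element_graph(fan5, 5, fan_network).components()
    new_mesh, dup_map = split_at_vertex(fan5, 5, comps)
    assert len(dup_map) == 2  # three groups -> two extra vertices
    for new, (orig, _) in dup_map.items():
        assert np.array_equal(new_mesh.vertices[new], fan5.vertices[orig])
    # one component keeps the original index
    assert any(5 in new_mesh.elements[e] for c in comps for e in c)


def test_split_at_vertex_single_component_is_identity(fan5):
    star = [0, 1, 2, 3, 4]
    new_mesh, dup_map = split_at_vertex(fan5, 5, [star])
    assert not dup_map
    assert np.array_equal(new_mesh.elements, fan5.elements)


def test_cross_centre_components(cross_tight, cross_leaky):
    mesh, network, expected = cross_tight
    for v in expected["cross_centres"]:
        lgraph = local_element_graph(mesh, v, network)
        assert len(lgraph.components()) == 4
        assert len(star_components(mesh, network, v)) == 4
    # both topologies share the identical split-edge set
    assert cross_leaky[1].faces == network.faces


def test_cross_split_group_counts(cross_tight, cross_leaky):
    for (mesh, network, expected) in (cross_tight, cross_leaky):
        result = split_mesh(mesh, network, assignment=expected["assignment"])
        for v in expected["cross_centres"]:
            groups = result.vertex_components[v]
            assert len(groups) == expected["components_per_centre"]


def test_fallback_2d_removes_collinear_edge():
    # lone horizontal split edge in a regular grid: the local graph at each
    # endpoint disconnects along the collinear opposite edge
    mesh = make_grid_2d(8, 1.0)

    def vid(i, j):
        return j * 9 + i

    network = FibrosisNetwork({tuple(sorted((vid(3, 4), vid(4, 4))))})
    lgraph = local_element_graph(mesh, vid(3, 4), network)
    assert len(lgraph.components()) == 1  # lone edge does not disconnect
    fallback_disconnect(lgraph, (vid(3, 4), vid(4, 4)), mesh.vertices)
    comps = lgraph.components()
    assert len(comps) == 2
    # the removed link is the one across the collinear edge to vid(2, 4):
    # its two elements must now lie in different components
    west = tuple(sorted((vid(2, 4), vid(3, 4))))
    adjacent = [
        e for e in range(mesh.n_elements)
        if set(west) <= set(int(x) for x in mesh.elements[e])
    ]
    comp_of = {e: i for i, c in enumerate(comps) for e in c}
    assert comp_of[adjacent[0]] != comp_of[adjacent[1]]


def test_fallback_3d_selects_coplanar_face(tet_fan):
    # split face (3,4,5) between e1 and e4 leaves them connected through
    # e2, e3; the coplanar face (1,3,5) is removed, giving {e1,e2}, {e3,e4}
    network = FibrosisNetwork({(3, 4, 5)})
    lgraph = local_element_graph(tet_fan, 5, network)
    assert lgraph.same_component(0, 3)
    fallback_disconnect(lgraph, (3, 4, 5), tet_fan.vertices)
    assert lgraph.components() == [(0, 1), (2, 3)]
    assert not lgraph.graph.has_edge(1, 2)  # the (1,3,5) link was cut


def test_fallback_noop_when_already_disconnected(tet_fan):
    network = FibrosisNetwork({(3, 4, 5)})
    lgraph = local_element_graph(tet_fan, 5, network)
    fallback_disconnect(lgraph, (3, 4, 5), tet_fan.vertices)
    edges_before = set(map(frozenset, lgraph.graph.edges))
    fallback_disconnect(lgraph, (3, 4, 5), tet_fan.vertices)
    assert set(map(frozenset, lgraph.graph.edges)) == edges_before


def test_straight_fence_duplicates_interior_vertices_once():
    mesh = make_grid_2d(8, 1.0)

    def vid(i, j):
        return j * 9 + i

    network = FibrosisNetwork(
        {tuple(sorted((vid(i, 4), vid(i + 1, 4)))) for i in range(2, 6)}
    )
    result = split_mesh(mesh, network)
    dup_counts = {}
    for _, (orig, _) in result.duplication_map.items():
        dup_counts[orig] = dup_counts.get(orig, 0) + 1
    for i in range(3, 6):  # interior fence vertices
        assert dup_counts[vid(i, 4)] == 1
    assert audit_tightness(result, network).passed


def test_empty_network_is_identity(lge_slab):
    slab, _ = lge_slab
    result = split_mesh(slab, FibrosisNetwork(set()))
    assert result.n_duplicates == 0
    assert np.array_equal(result.mesh.elements, slab.elements)
    assert audit_tightness(result, FibrosisNetwork(set())).passed


def test_split_preserves_geometry(cross_tight):
    mesh, network, _ = cross_tight
    result = split_mesh(mesh, network)
    assert np.isclose(result.mesh.measures().sum(), mesh.measures().sum())
    for new, (orig, _) in result.duplication_map.items():
        assert np.array_equal(result.mesh.vertices[new], mesh.vertices[orig])


def test_split_is_idempotent(cross_tight):
    mesh, network, _ = cross_tight
    result = split_mesh(mesh, network)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # re-split warns about boundary faces
        again = split_mesh(result.mesh, network)
    assert again.n_duplicates == 0
    assert np.array_equal(again.mesh.elements, result.mesh.elements)


def test_boundary_network_faces_are_skipped_with_warning():
    mesh = make_grid_2d(3, 1.0)
    boundary_edge = (0, 1)  # bottom edge of the grid
    with pytest.warns(UserWarning, match="boundary"):
        result = split_mesh(mesh, FibrosisNetwork({boundary_edge}))
    assert result.n_duplicates == 0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_duplicates_refine_star_component_oracle(lge_slab, seed):
    """The splitter never produces fewer copies at a vertex than the
    brute-force star-component oracle demands; fallback cuts at cleft ends
    (here and at neighbouring vertices) may only refine the partition."""
    slab, intensity = lge_slab
    pmap = probability_map(slab, intensity, 0.5)
    network = sample_network(pmap, seed)
    result = split_mesh(slab, network)
    dup_counts = {}
    for _, (orig, _) in result.duplication_map.items():
        dup_counts[orig] = dup_counts.get(orig, 0) + 1
    checked = 0
    for v in sorted({v for fk in network.faces for v in fk}):
        comps = star_components(slab, network, v)
        assert dup_counts.get(v, 0) >= len(comps) - 1
        checked += 1
    assert checked > 0


def test_duplicates_equal_star_oracle_without_fallback():
    """On a complete planar fence (no cleft ends, so no fallback), the
    number of copies at every fence vertex equals the star-component count
    of the brute-force global element graph minus one."""
    slab = make_slab_3d((3.0, 3.0, 2.0), 1.0)
    z_mid = np.isclose(slab.vertices[:, 2], 1.0)
    faces = set()
    import itertools

    for elem in slab.elements:
        for c in itertools.combinations(sorted(int(v) for v in elem), 3):
            if all(z_mid[v] for v in c):
                faces.add(c)
    network = FibrosisNetwork(faces)
    result = split_mesh(slab, network)
    assert not result.fallback_vertices
    dup_counts = {}
    for _, (orig, _) in result.duplication_map.items():
        dup_counts[orig] = dup_counts.get(orig, 0) + 1
    for v in sorted({v for fk in network.faces for v in fk}):
        comps = star_components(slab, network, v)
        assert dup_counts.get(v, 0) == len(comps) - 1 == 1
    assert audit_tightness(result, network).passed


def test_enclosed_element_is_pruned():
    slab = make_slab_3d((3.0, 3.0, 3.0), 1.0)
    target = 5 * 13  # first tet of the central cell
    faces = [
        tuple(sorted(int(x) for x in np.delete(slab.elements[target], k)))
        for k in range(4)
    ]
    network = FibrosisNetwork(set(faces))
    result = split_mesh(slab, network)
    pruned = remove_isolated_components(result)
    assert len(pruned.removed_elements) >= 1
    assert pruned.mesh.n_elements < result.mesh.n_elements
    # the remaining mesh loses exactly the isolated elements' volume
    lost = result.mesh.measures()[pruned.removed_elements].sum()
    assert np.isclose(
        pruned.mesh.measures().sum() + lost, slab.measures().sum()
    )
    pruned.mesh.validate()


def test_prune_without_isolation_is_identity(cross_tight):
    mesh, network, _ = cross_tight
    result = split_mesh(mesh, network)
    pruned = remove_isolated_components(result)
    assert len(pruned.removed_elements) == 0
    assert pruned.mesh.n_elements == result.mesh.n_elements


def test_audit_flags_leaky_centres_only(cross_tight, cross_leaky):
    mesh, network, expected = cross_leaky
    result = split_mesh(mesh, network, assignment="leaky")
    report = audit_tightness(result, network)
    assert not report.passed
    assert not report.face_failures  # faces themselves are split
    assert {f["vertex"] for f in report.vertex_failures} == set(
        expected["cross_centres"]
    )
    tight_result = split_mesh(*cross_tight[:2])
    assert audit_tightness(tight_result, cross_tight[1]).passed
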