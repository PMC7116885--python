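"""Brute-force oracles used to cross-check the package's fast algorithms."""

import itertools

import networkx as nx
import numpy as np

from fibroclefts.mesh import face_key


def brute_adjacency(mesh):
    """O(elements^2) face matching: face key -> sorted element ids."""
    faces = {}
    m = mesh.n_elements
    dim = mesh.dim
    elem_sets = [set(int(v) for v in e) for e in mesh.elements]
    for a in range(m):
        for b in range(a + 1, m):
            shared = elem_sets[a] & elem_sets[b]
            if len(shared) == dim:
                faces[face_key(shared)] = [a, b]
    for e, es in enumerate(elem_sets):
        for c in itertools.combinations(sorted(es), dim):
            faces.setdefault(face_key(c), [e])
    return faces


def global_element_graph(mesh, network):
    """Element graph with links across every non-network interior face."""
    g = nx.Graph()
    g.add_nodes_from(range(mesh.n_elements))
    for fk, els in brute_adjacency(mesh).items():
        if len(els) == 2 and fk not in network.faces:
            g.add_edge(*els)
    return g


def star_components(mesh, network, vertex):
    """Components of the vertex star inside the global element graph."""
    g = global_element_graph(mesh, network)
    star = [e for e in range(mesh.n_elements) if vertex in mesh.elements[e]]
    sub = g.subgraph(star)
    return sorted(tuple(sorted(c)) for c in nx.connected_components(sub))


def count_upstrokes(trace, threshold=0.0):
    """Number of upward threshold crossings in a sampled voltage trace."""
    trace = np.asarray(trace)
    return int(np.sum((trace[:-1] < threshold) & (trace[1:] >= threshold)))
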