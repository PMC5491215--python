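"""Independent brute-force oracles used to validate the geometry kernels.

These deliberately avoid the package's closed-form shortest-path machinery:
distances come from Dijkstra on graphs with temporary vertices inserted at
the query locations, and m(u, t) / the circumradius come from a dense
discretization of the network.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra


def split_graph(net, locations):
    """networkx graph of the network with temporary nodes ('loc', i) inserted
    at the given (segment, offset) locations by splitting their segments."""
    g = nx.Graph()
    by_seg: dict[int, list[tuple[float, object]]] = {}
    for i, loc in enumerate(locations):
        by_seg.setdefault(loc.segment, []).append((loc.offset, ("loc", i)))
    for s in range(net.n_segments):
        a, b = map(int, net.segments[s])
        if s not in by_seg:
            g.add_edge(a, b, weight=float(net.lengths[s]))
            continue
        chain = sorted(by_seg[s]) if s in by_seg else []
        prev_node, prev_off = a, 0.0
        for off, node in chain:
            g.add_edge(prev_node, node, weight=float(off - prev_off))
            prev_node, prev_off = node, off
        g.add_edge(prev_node, b, weight=float(net.lengths[s] - prev_off))
    return g


def oracle_distance(net, u, v):
    """Shortest-path distance via networkx Dijkstra with temporary vertices."""
    g = split_graph(net, [u, v])
    # zero-weight edges from coincident offsets are fine for dijkstra
    return nx.dijkstra_path_length(g, ("loc", 0), ("loc", 1))


def densify(net, eps):
    """Discretize the network at ~eps spacing.

    Returns (graph csr matrix, node distances-from-root placeholder,
    node_seg, node_off) where nodes 0..V-1 are the original vertices and the
    rest are interior samples.
    """
    rows, cols, w = [], [], []
    node_seg = [-1] * net.n_vertices
    node_off = [0.0] * net.n_vertices
    nid = net.n_vertices
    for s in range(net.n_segments):
        a, b = map(int, net.segments[s])
        length = float(net.lengths[s])
        k = max(int(np.floor(length / eps)), 1)
        offs = np.linspace(0.0, length, k + 1)[1:-1]
        prev, prev_off = a, 0.0
        for off in offs:
            rows.append(prev)
            cols.append(nid)
            w.append(off - prev_off)
            node_seg.append(s)
            node_off.append(float(off))
            prev, prev_off = nid, off
            nid += 1
        rows.append(prev)
        cols.append(b)
        w.append(length - prev_off)
    n = nid
    mat = csr_matrix((w + w, (rows + cols, cols + rows)), shape=(n, n))
    return mat, np.array(node_seg), np.array(node_off)


def _attach_point(mat, node_seg, node_off, loc):
    """Augment the densified graph with one extra node at ``loc``."""
    n = mat.shape[0]
    same = np.nonzero(node_seg == loc.segment)[0]
    coo = mat.tocoo()
    rows = list(coo.row)
    cols = list(coo.col)
    w = list(coo.data)
    # connect to the nearest samples on either side (or segment endpoints)
    offs = node_off[same]
    left = same[offs <= loc.offset]
    right = same[offs > loc.offset]
    targets = []
    if len(left):
        i = left[np.argmax(node_off[left])]
        targets.append((int(i), loc.offset - float(node_off[i])))
    if len(right):
        i = right[np.argmin(node_off[right])]
        targets.append((int(i), float(node_off[i]) - loc.offset))
    # always include the segment's endpoint vertices as fallbacks
    # (handles segments with no interior samples on one side)
    return n, rows, cols, w, targets


def oracle_m(net, u, t, eps=0.01):
    """m(u, t) by counting connected clusters of discretization samples whose
    distance from u is within eps/2 of t."""
    mat, node_seg, node_off = densify(net, eps)
    n, rows, cols, w, targets = _attach_point(mat, node_seg, node_off, u)
    a, b = map(int, net.segments[u.segment])
    targets.append((a, float(u.offset)))
    targets.append((b, float(net.lengths[u.segment] - u.offset)))
    for i, wt in targets:
        rows.extend([n, i])
        cols.extend([i, n])
        w.extend([wt, wt])
    aug = csr_matrix((w, (rows, cols)), shape=(n + 1, n + 1))
    dist = dijkstra(aug, directed=False, indices=n)
    marked = np.nonzero(np.abs(dist[:n] - t) <= eps / 2.0)[0]
    if len(marked) == 0:
        return 0
    sub = aug[marked][:, marked]
    ncomp, _ = connected_components(sub, directed=False)
    return int(ncomp)


def oracle_circumradius(net, eps=0.002):
    """min-over-locations of max-over-locations distance, on a dense
    discretization.  The farthest point from anywhere on a tree is a leaf,
    so eccentricities are maxima over distances from the leaf vertices."""
    mat, _, _ = densify(net, eps)
    leaves = np.nonzero(net.vertex_degrees() == 1)[0]
    dist = dijkstra(mat, directed=False, indices=leaves)
    ecc = dist.max(axis=0)
    return float(ecc.min())
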