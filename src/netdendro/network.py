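"""Geometry and topology of 3D linear networks.

A linear network is a union of straight line segments in 3D space; here it is
always an acyclic connected network (a tree), which is the natural domain for
dendritic arborizations.  All lengths and coordinates are in micrometres.

The module provides construction and validation, shortest-path (geodesic)
distances between arbitrary on-network locations, the exact-distance count
``m(u, t)`` used by the geometrically corrected K function, the network
circumradius, and snapping of off-network 3D points onto the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

# Tolerance (in μm) below which a location is considered to sit exactly on a
# vertex, and two network distances are considered exactly equal.  Segment
# lengths are O(1)–O(100) μm, so 1e-9 is far below any geometric feature.
VERTEX_TOL = 1e-9


class NetworkError(ValueError):
    """Raised for invalid network topology or off-network locations."""


@dataclass(frozen=True)
class Point3:
    """A point in 3D Euclidean space (μm)."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class NetworkLocation:
    """A location on a network: ``offset`` μm along segment ``segment``.

    The offset is measured from the segment's first endpoint.  Locations that
    coincide with a shared vertex have several (segment, offset)
    representations; :meth:`LinearNetwork3D.canonicalize` maps them to a
    unique one so equality is well defined.
    """

    segment: int
    offset: float


class LinearNetwork3D:
    """A connected acyclic linear network (geodesic tree) embedded in 3D.

    Parameters
    ----------
    vertices:
        ``(V, 3)`` array of vertex coordinates in μm.
    segments:
        ``(S, 2)`` integer array of vertex-index pairs.  Segment arc lengths
        are the Euclidean distances between the endpoint coordinates.
    root:
        Optional root location (the soma attachment for dendrites).

    Use :func:`build_network` rather than calling this directly: it validates
    connectivity and acyclicity.
    """

    def __init__(self, vertices: np.ndarray, segments: np.ndarray,
                 root: NetworkLocation | None = None):
        self.vertices = np.asarray(vertices, dtype=float)
        self.segments = np.asarray(segments, dtype=np.intp)
        a, b = self.segments[:, 0], self.segments[:, 1]
        self.lengths = np.linalg.norm(self.vertices[b] - self.vertices[a], axis=1)
        self.total_length = float(self.lengths.sum())
        self.root = root
        self._vertex_dist: np.ndarray | None = None
        self._degrees: np.ndarray | None = None

    # ------------------------------------------------------------------
    # basic properties
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def vertex_degrees(self) -> np.ndarray:
        if self._degrees is None:
            deg = np.zeros(self.n_vertices, dtype=int)
            np.add.at(deg, self.segments[:, 0], 1)
            np.add.at(deg, self.segments[:, 1], 1)
            self._degrees = deg
        return self._degrees

    def branch_point_count(self) -> int:
        """Number of vertices of degree >= 3 (bifurcations)."""
        return int(np.sum(self.vertex_degrees() >= 3))

    # ------------------------------------------------------------------
    # locations
    def validate_location(self, u: NetworkLocation) -> None:
        if not (0 <= u.segment < self.n_segments):
            raise NetworkError(f"segment index {u.segment} not on the network")
        if not (-VERTEX_TOL <= u.offset <= self.lengths[u.segment] + VERTEX_TOL):
            raise NetworkError(
                f"offset {u.offset} outside segment {u.segment} "
                f"(length {self.lengths[u.segment]:.6g})")

    def location_vertex(self, u: NetworkLocation) -> int | None:
        """Vertex index if ``u`` sits on a vertex, else None."""
        if u.offset <= VERTEX_TOL:
            return int(self.segments[u.segment, 0])
        if u.offset >= self.lengths[u.segment] - VERTEX_TOL:
            return int(self.segments[u.segment, 1])
        return None

    def vertex_location(self, v: int) -> NetworkLocation:
        """Canonical NetworkLocation of vertex ``v``."""
        hits = np.nonzero((self.segments[:, 0] == v) | (self.segments[:, 1] == v))[0]
        if len(hits) == 0:
            raise NetworkError(f"vertex {v} is isolated")
        s = int(hits[0])
        off = 0.0 if self.segments[s, 0] == v else float(self.lengths[s])
        return NetworkLocation(s, off)

    def canonicalize(self, u: NetworkLocation) -> NetworkLocation:
        """Unique representation: vertex locations use the lowest incident
        segment id; interior locations are returned unchanged."""
        self.validate_location(u)
        v = self.location_vertex(u)
        if v is None:
            return u
        return self.vertex_location(v)

    def same_location(self, u: NetworkLocation, v: NetworkLocation) -> bool:
        cu, cv = self.canonicalize(u), self.canonicalize(v)
        return cu.segment == cv.segment and abs(cu.offset - cv.offset) <= VERTEX_TOL

    def coordinates(self, u: NetworkLocation) -> np.ndarray:
        """3D coordinates of an on-network location."""
        self.validate_location(u)
        a, b = self.segments[u.segment]
        frac = u.offset / self.lengths[u.segment]
        return (1 - frac) * self.vertices[a] + frac * self.vertices[b]

    # ------------------------------------------------------------------
    # distances
    def vertex_distance_matrix(self) -> np.ndarray:
        """All-pairs shortest-path distances between vertices (cached)."""
        if self._vertex_dist is None:
            a, b = self.segments[:, 0], self.segments[:, 1]
            w = self.lengths
            n = self.n_vertices
            mat = csr_matrix(
                (np.concatenate([w, w]),
                 (np.concatenate([a, b]), np.concatenate([b, a]))),
                shape=(n, n))
            self._vertex_dist = dijkstra(mat, directed=False)
        return self._vertex_dist

    def distances_to_vertices(self, u: NetworkLocation) -> np.ndarray:
        """Shortest-path distance from ``u`` to every vertex, shape (V,)."""
        self.validate_location(u)
        D = self.vertex_distance_matrix()
        a, b = self.segments[u.segment]
        off = u.offset
        return np.minimum(off + D[a], (self.lengths[u.segment] - off) + D[b])

    def distances_from(self, u: NetworkLocation,
                       seg: np.ndarray, off: np.ndarray) -> np.ndarray:
        """Vectorized shortest-path distances from ``u`` to locations given as
        parallel arrays of segment ids and offsets."""
        seg = np.asarray(seg, dtype=np.intp)
        off = np.asarray(off, dtype=float)
        dv = self.distances_to_vertices(u)
        a, b = self.segments[seg, 0], self.segments[seg, 1]
        d = np.minimum(dv[a] + off, dv[b] + (self.lengths[seg] - off))
        same = seg == u.segment
        if np.any(same):
            # within one segment of a tree the direct arc is the geodesic
            d = np.where(same, np.abs(off - u.offset), d)
        return d


def build_network(vertices, edges, root_vertex: int | None = None) -> LinearNetwork3D:
    """Construct and validate a 3D linear network (tree).

    Parameters
    ----------
    vertices:
        Sequence of 3D coordinates (``Point3`` or length-3 sequences), μm.
    edges:
        Sequence of vertex-index pairs; each becomes a straight segment whose
        arc length is the Euclidean distance between its endpoints.
    root_vertex:
        Optional index of the root vertex (tree origin, e.g. the soma).

    Raises
    ------
    NetworkError
        If any edge has identical or invalid endpoints, any segment has zero
        length, or the graph is not a connected acyclic network.
    """
    coords = np.array([p.as_array() if isinstance(p, Point3) else np.asarray(p, float)
                       for p in vertices], dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise NetworkError("vertices must be 3D coordinates")
    if not np.all(np.isfinite(coords)):
        raise NetworkError("vertex coordinates must be finite")
    segs = np.asarray(edges, dtype=np.intp)
    if segs.ndim != 2 or segs.shape[1] != 2:
        raise NetworkError("edges must be pairs of vertex indices")
    n = len(coords)
    if segs.size and (segs.min() < 0 or segs.max() >= n):
        raise NetworkError("edge refers to a nonexistent vertex")
    if np.any(segs[:, 0] == segs[:, 1]):
        raise NetworkError("edge endpoints must be distinct")
    lengths = np.linalg.norm(coords[segs[:, 1]] - coords[segs[:, 0]], axis=1)
    if np.any(lengths <= 0):
        bad = int(np.argmin(lengths))
        raise NetworkError(f"segment {bad} has zero length (coincident endpoints)")

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, segs))
    if g.number_of_edges() != len(segs):
        raise NetworkError("duplicate edges form a degenerate cycle")
    if not nx.is_connected(g):
        raise NetworkError("network is disconnected (infinite shortest-path distances)")
    if not nx.is_tree(g):
        raise NetworkError("network contains a cycle; only acyclic networks (trees) are supported")

    net = LinearNetwork3D(coords, segs)
    if root_vertex is not None:
        if not (0 <= root_vertex < n):
            raise NetworkError(f"root vertex {root_vertex} does not exist")
        net.root = net.vertex_location(int(root_vertex))
    return net


def shortest_path_distance(net: LinearNetwork3D, u: NetworkLocation,
                           v: NetworkLocation) -> float:
    """Geodesic (shortest-path) distance along the network between two
    on-network locations, in μm."""
    net.validate_location(u)
    net.validate_location(v)
    d = net.distances_from(u, np.array([v.segment]), np.array([v.offset]))
    return float(d[0])


def distance_to_root(net: LinearNetwork3D, u) -> float | np.ndarray:
    """Shortest-path distance from location(s) ``u`` to the network root.

    Accepts a single :class:`NetworkLocation` or a sequence of them; the
    vectorized form returns an array.
    """
    if net.root is None:
        raise NetworkError("network has no root; set one via build_network(root_vertex=...)")
    if isinstance(u, NetworkLocation):
        return shortest_path_distance(net, net.root, u)
    seg = np.array([loc.segment for loc in u], dtype=np.intp)
    off = np.array([loc.offset for loc in u], dtype=float)
    return net.distances_from(net.root, seg, off)


def _distance_intervals(net: LinearNetwork3D, u: NetworkLocation):
    """Open intervals of distances-from-``u`` covered by segment interiors.

    On a tree every segment not containing ``u`` is entered through exactly
    one endpoint, so its interior covers (d_enter, d_enter + length) exactly
    once.  The segment carrying ``u`` contributes the two half-intervals on
    either side of ``u``.  Returns (enters, ends) arrays.
    """
    dv = net.distances_to_vertices(u)
    a, b = net.segments[:, 0], net.segments[:, 1]
    enters = np.minimum(dv[a], dv[b])
    ends = enters + net.lengths
    s = u.segment
    own = [(0.0, u.offset), (0.0, net.lengths[s] - u.offset)]
    keep = np.ones(net.n_segments, dtype=bool)
    keep[s] = False
    enters = np.concatenate([enters[keep], [e for e, _ in own]])
    ends = np.concatenate([ends[keep], [e + w for e, w in own]])
    pos = ends - enters > VERTEX_TOL
    return enters[pos], ends[pos], dv


def count_at_distance(net: LinearNetwork3D, u: NetworkLocation, t: float) -> int:
    """The exact-distance count ``m(u, t)``: the number of network locations
    at shortest-path distance exactly ``t`` from ``u``.

    ``m(u, 0) = 1`` (the point itself).  For ``t > 0`` each segment interior
    crossed by the distance-``t`` front contributes one location, and each
    vertex at distance exactly ``t`` counts once (set cardinality, regardless
    of how many branches meet there).
    """
    if t < 0:
        raise ValueError("distance t must be nonnegative")
    net.validate_location(u)
    if t <= VERTEX_TOL:
        return 1
    enters, ends, dv = _distance_intervals(net, u)
    interior = np.sum((t - enters > VERTEX_TOL) & (ends - t > VERTEX_TOL))
    at_vertex = np.sum(np.abs(dv - t) <= VERTEX_TOL)
    return int(interior + at_vertex)


def counts_at_distances(net: LinearNetwork3D, u: NetworkLocation,
                        ts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`count_at_distance` for an array of distances."""
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("distances must be nonnegative")
    enters, ends, dv = _distance_intervals(net, u)
    enters = np.sort(enters)
    ends = np.sort(ends)
    dvs = np.sort(dv)
    n_open = (np.searchsorted(enters, ts - VERTEX_TOL, side="left")
              - np.searchsorted(ends, ts + VERTEX_TOL, side="right"))
    n_vert = (np.searchsorted(dvs, ts + VERTEX_TOL, side="right")
              - np.searchsorted(dvs, ts - VERTEX_TOL, side="left"))
    m = n_open + n_vert
    return np.where(ts <= VERTEX_TOL, 1, m).astype(np.intp)


def eccentricity(net: LinearNetwork3D, u: NetworkLocation) -> float:
    """Largest shortest-path distance from ``u`` to any point of the network.

    On a tree the farthest point from any location is a vertex (distance is
    monotone along every segment not containing it), so this is the maximum
    over vertex distances.
    """
    return float(net.distances_to_vertices(u).max())


def circumradius(net: LinearNetwork3D) -> float:
    """Radius R of the smallest shortest-path disc covering the network.

    For a geodesic tree R equals half the network diameter, computed exactly
    by a double sweep: the farthest vertex from an arbitrary vertex is one
    diameter endpoint, and the farthest vertex from that is the other.
    """
    D = net.vertex_distance_matrix()
    a = int(np.argmax(D[0]))
    diam = float(D[a].max())
    return diam / 2.0


def snap_to_network(net: LinearNetwork3D, p, max_dist: float) -> NetworkLocation:
    """Project a 3D point onto the nearest point of the network.

    Returns the :class:`NetworkLocation` minimizing the Euclidean distance
    from ``p`` to the segments; ties broken by lowest segment id, then lowest
    offset.  Raises :class:`NetworkError` if the nearest distance exceeds
    ``max_dist``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    q = p.as_array() if isinstance(p, Point3) else np.asarray(p, dtype=float)
    A = net.vertices[net.segments[:, 0]]
    B = net.vertices[net.segments[:, 1]]
    AB = B - A
    denom = np.einsum("ij,ij->i", AB, AB)
    tt = np.clip(np.einsum("ij,ij->i", q[None, :] - A, AB) / denom, 0.0, 1.0)
    proj = A + tt[:, None] * AB
    dist = np.linalg.norm(proj - q[None, :], axis=1)
    order = np.lexsort((tt, dist))  # min distance, then lowest offset; stable in id
    best = int(order[0])
    # lexsort breaks distance ties by offset; enforce segment-id priority among
    # exact distance ties
    ties = np.nonzero(dist <= dist[best] + VERTEX_TOL)[0]
    best = int(ties.min())
    if dist[best] > max_dist:
        raise NetworkError(
            f"point {tuple(np.round(q, 4))} is {dist[best]:.4g} μm from the network "
            f"(max_dist {max_dist})")
    return NetworkLocation(best, float(tt[best] * net.lengths[best]))
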