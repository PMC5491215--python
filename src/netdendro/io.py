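"""Readers/writers for standard formats and descriptive statistics.

Morphologies travel as standard 7-column SWC files (id, type, x, y, z,
radius, parent; '#' comments; parent −1 marks the root).  Events travel as
CSV with header ``x,y,z`` (3D coordinates snapped onto the network) or
``segment,offset``.  Summary curves are written as CSV with columns
``d,value,theoretical[,lower,upper]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (LinearNetwork3D, NetworkError, NetworkLocation,
                      build_network, circumradius, snap_to_network)
from .intensity import NetworkPointPattern, uniform_intensity


class SWCError(ValueError):
    """Raised for malformed SWC files; messages carry line numbers."""


def read_swc(path) -> LinearNetwork3D:
    """Read an SWC morphology into a rooted :class:`LinearNetwork3D`.

    Each parent-child link becomes one straight segment.  Consecutive nodes
    with duplicate coordinates are collapsed with a warning (zero-length
    segments are not representable).
    """
    ids: dict[int, int] = {}
    coords: list[np.ndarray] = []
    parents: list[tuple[int, int, int]] = []  # (line_no, node_idx, parent_id)
    roots: list[int] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"{path}:{line_no}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0])
                xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"{path}:{line_no}: {exc}") from None
            if nid in ids:
                raise SWCError(f"{path}:{line_no}: duplicate node id {nid}")
            ids[nid] = len(coords)
            coords.append(xyz)
            if parent == -1:
                roots.append(len(coords) - 1)
            else:
                parents.append((line_no, len(coords) - 1, parent))
    if not coords:
        raise SWCError(f"{path}: no nodes")
    if len(roots) != 1:
        raise SWCError(f"{path}: expected exactly one root (parent -1), found {len(roots)}")

    # collapse consecutive duplicate coordinates (child == parent position)
    alias = list(range(len(coords)))
    edges = []
    collapsed = 0
    for line_no, child, parent_id in parents:
        if parent_id not in ids:
            raise SWCError(f"{path}:{line_no}: parent id {parent_id} does not exist")
        p = alias[ids[parent_id]]
        if np.linalg.norm(coords[child] - coords[p]) <= 1e-12:
            alias[child] = p
            collapsed += 1
            continue
        edges.append((p, child))
    if collapsed:
        warnings.warn(f"{path}: collapsed {collapsed} zero-length SWC link(s)")
    keep = sorted({alias[i] for i in range(len(coords))
                   if alias[i] == i})
    remap = {old: new for new, old in enumerate(keep)}
    vertices = np.array([coords[i] for i in keep])
    edges = [(remap[a], remap[b]) for a, b in edges]
    try:
        return build_network(vertices, edges, root_vertex=remap[alias[roots[0]]])
    except NetworkError as exc:
        raise SWCError(f"{path}: {exc}") from None


def write_swc(net: LinearNetwork3D, path) -> None:
    """Write a rooted network as SWC, one node per vertex in depth-first
    order from the root; the radius column is a 0.5 μm placeholder."""
    if net.root is None:
        raise NetworkError("cannot write SWC for an unrooted network")
    root_v = net.location_vertex(net.root)
    if root_v is None:
        raise NetworkError("SWC export requires the root to sit on a vertex")
    adj: dict[int, list[int]] = {}
    for a, b in net.segments:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    order: list[tuple[int, int]] = []  # (vertex, parent vertex or -1)
    stack = [(root_v, -1)]
    seen = set()
    while stack:
        v, parent = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        order.append((v, parent))
        for w in sorted(adj.get(v, []), reverse=True):
            if w not in seen:
                stack.append((w, v))
    swc_id = {v: i + 1 for i, (v, _) in enumerate(order)}
    with open(path, "w") as fh:
        fh.write("# SWC exported by netdendro\n")
        fh.write("# id type x y z radius parent\n")
        for v, parent in order:
            x, y, z = net.vertices[v]
            stype = 1 if parent == -1 else 3
            pid = -1 if parent == -1 else swc_id[parent]
            fh.write(f"{swc_id[v]} {stype} {x:.9g} {y:.9g} {z:.9g} 0.5 {pid}\n")


def read_events(path, net: LinearNetwork3D, max_snap: float = 5.0
                ) -> NetworkPointPattern:
    """Read an events CSV (``x,y,z`` or ``segment,offset``) as a pattern.

    3D rows are snapped onto the network (error if farther than ``max_snap``
    μm); segment/offset rows are validated directly.  Errors name the
    offending CSV row.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    events = []
    if cols[:3] == ["x", "y", "z"]:
        for row_no, (_, row) in enumerate(df.iterrows(), start=2):
            try:
                events.append(snap_to_network(
                    net, np.array([row.iloc[0], row.iloc[1], row.iloc[2]], float),
                    max_dist=max_snap))
            except NetworkError as exc:
                raise NetworkError(f"{path} row {row_no}: {exc}") from None
    elif cols[:2] == ["segment", "offset"]:
        for row_no, (_, row) in enumerate(df.iterrows(), start=2):
            loc = NetworkLocation(int(row.iloc[0]), float(row.iloc[1]))
            try:
                net.validate_location(loc)
            except NetworkError as exc:
                raise NetworkError(f"{path} row {row_no}: {exc}") from None
            events.append(loc)
    else:
        raise ValueError(f"{path}: expected header x,y,z or segment,offset, "
                         f"got {list(df.columns)}")
    return NetworkPointPattern(net, events)


def write_events(pattern: NetworkPointPattern, path) -> None:
    """Write a pattern as a segment,offset CSV."""
    pd.DataFrame({"segment": pattern.seg, "offset": pattern.off}).to_csv(
        path, index=False)


def write_curve(obj, path) -> None:
    """Write a SummaryFunction or EnvelopeResult as a curves CSV."""
    obj.to_frame().to_csv(path, index=False)


@dataclass
class DescribeRecord:
    """Descriptive statistics of a network + pattern: event count, total
    length (μm), mean intensity (events/μm), circumradius (μm), and number of
    branching points (vertices of degree ≥ 3)."""

    n: float
    total_length: float
    mean_intensity: float
    circumradius: float
    branch_points: float


def describe(net: LinearNetwork3D, pattern: NetworkPointPattern) -> DescribeRecord:
    """Descriptive statistics for one network and its pattern."""
    return DescribeRecord(
        n=pattern.n,
        total_length=net.total_length,
        mean_intensity=uniform_intensity(pattern),
        circumradius=circumradius(net),
        branch_points=net.branch_point_count(),
    )


def mean_describe(records: list[DescribeRecord]) -> DescribeRecord:
    """Field-wise arithmetic mean of describe records (a summary row).

    Note the mean record's ``mean_intensity`` is the average of the member
    intensities, not mean n over mean length.
    """
    if not records:
        raise ValueError("no records")
    return DescribeRecord(
        n=float(np.mean([r.n for r in records])),
        total_length=float(np.mean([r.total_length for r in records])),
        mean_intensity=float(np.mean([r.mean_intensity for r in records])),
        circumradius=float(np.mean([r.circumradius for r in records])),
        branch_points=float(np.mean([r.branch_points for r in records])),
    )
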