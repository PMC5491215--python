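"""Network K functions.

Three second-order summaries for point patterns on linear networks:

* ``k_net`` — the empirical network K function, the direct analogue of
  Ripley's K with shortest-path distances; its value depends on the network's
  geometry, so it is not comparable across networks.
* ``k_corrected`` — the geometrically corrected K function K_L, where each
  pair (x_i, x_j) is down-weighted by m(x_i, d_ij), the number of network
  locations at exactly the inter-event distance from x_i.  Under a
  homogeneous Poisson process K_L(d) = d for 0 ≤ d ≤ R (the circumradius),
  which makes K_L comparable across different networks.
* ``k_inhom`` — the inhomogeneous version K_LI, additionally weighting each
  pair by 1/(λ(x_i)λ(x_j)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import LinearNetwork3D, circumradius
from .intensity import NetworkPointPattern

_R_TOL = 1e-9


@dataclass
class DistanceGrid:
    """A strictly increasing grid of network distances (μm), starting ≥ 0."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("grid must be a nonempty 1D array")
        if self.values[0] < 0 or np.any(np.diff(self.values) <= 0):
            raise ValueError("grid values must be strictly increasing and nonnegative")

    @property
    def r_max(self) -> float:
        return float(self.values[-1])


def default_grid(net: LinearNetwork3D, n_points: int = 512,
                 rmax_frac: float = 0.98) -> DistanceGrid:
    """Equispaced grid on [0, rmax_frac · R]; the 2%-below-circumradius
    default keeps the corrected estimators inside their validity range."""
    r = circumradius(net)
    return DistanceGrid(np.linspace(0.0, rmax_frac * r, n_points))


@dataclass
class SummaryFunction:
    """A K-type summary evaluated on a distance grid.

    ``theoretical`` holds the Poisson reference (K_L(d) = d) for the
    corrected versions and is None for the uncorrected K_net, whose Poisson
    expectation depends on the network geometry.
    """

    grid: DistanceGrid
    values: np.ndarray
    kind: str  # "Knet" | "KL" | "KLI"
    theoretical: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        data = {"d": self.grid.values, "value": self.values}
        if self.theoretical is not None:
            data["theoretical"] = self.theoretical
        return pd.DataFrame(data)


def _event_vertex_distances(pattern: NetworkPointPattern):
    """Distances from every event to every vertex, plus the all-pairs
    inter-event distance matrix."""
    net = pattern.network
    seg, off = pattern.seg, pattern.off
    D = net.vertex_distance_matrix()
    a, b = net.segments[seg, 0], net.segments[seg, 1]
    lens = net.lengths[seg]
    dv = np.minimum(off[:, None] + D[a], (lens - off)[:, None] + D[b])
    d = np.minimum(dv[:, a] + off[None, :], dv[:, b] + (lens - off)[None, :])
    same = seg[:, None] == seg[None, :]
    if np.any(same):
        direct = np.abs(off[:, None] - off[None, :])
        d = np.where(same, direct, d)
    d = np.minimum(d, d.T)  # enforce exact symmetry
    np.fill_diagonal(d, 0.0)
    return dv, d


def pairwise_network_distances(pattern: NetworkPointPattern) -> np.ndarray:
    """All-pairs shortest-path distances between events, shape (n, n)."""
    return _event_vertex_distances(pattern)[1]


def _pair_m_counts(pattern: NetworkPointPattern, dists: np.ndarray,
                   dv: np.ndarray | None = None) -> np.ndarray:
    """m(x_i, d_ij) for every ordered pair, shape (n, n); diagonal is 1.

    On a tree every segment not carrying x_i covers the open distance range
    (min(dv[a], dv[b]), min + length) exactly once, and the carrying segment
    contributes its two half-intervals; a count queries how many of those
    open intervals contain d_ij, plus vertices at exactly d_ij.
    """
    from .network import VERTEX_TOL

    net = pattern.network
    n = pattern.n
    if dv is None:
        dv, _ = _event_vertex_distances(pattern)
    a, b = net.segments[:, 0], net.segments[:, 1]
    enters = np.minimum(dv[:, a], dv[:, b])          # (n, S)
    ends = enters + net.lengths[None, :]
    # replace each event's own segment by its two half-intervals
    rows = np.arange(n)
    own_len = net.lengths[pattern.seg]
    enters[rows, pattern.seg] = 0.0
    ends[rows, pattern.seg] = np.maximum(pattern.off, own_len - pattern.off)
    extra_end = np.minimum(pattern.off, own_len - pattern.off)
    enters = np.sort(np.column_stack([enters, np.zeros(n)]), axis=1)
    ends = np.sort(np.column_stack([ends, extra_end]), axis=1)
    dvs = np.sort(dv, axis=1)

    m = np.empty((n, n), dtype=np.intp)
    for i in range(n):
        t = dists[i]
        n_open = (np.searchsorted(enters[i], t - VERTEX_TOL, side="left")
                  - np.searchsorted(ends[i], t + VERTEX_TOL, side="right"))
        n_vert = (np.searchsorted(dvs[i], t + VERTEX_TOL, side="right")
                  - np.searchsorted(dvs[i], t - VERTEX_TOL, side="left"))
        m[i] = n_open + n_vert
    m[dists <= VERTEX_TOL] = 1  # m(u, 0) = 1, covers the diagonal
    return m


def _accumulate(grid: DistanceGrid, dists: np.ndarray,
                weights: np.ndarray) -> np.ndarray:
    """Sum of weights over ordered pairs with d_ij ≤ d, per grid value."""
    gv = grid.values
    idx = np.searchsorted(gv, dists, side="left")  # first grid point >= d_ij
    inside = idx < len(gv)
    per_point = np.bincount(idx[inside], weights=weights[inside],
                            minlength=len(gv))
    return np.cumsum(per_point)


def _offdiag(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    return a[~np.eye(n, dtype=bool)]


def k_net(pattern: NetworkPointPattern, grid: DistanceGrid) -> SummaryFunction:
    """Empirical network K function (no geometric correction)::

        K̂_net(d) = |L| / (n(n−1)) · Σ_i Σ_{j≠i} 1{d_L(x_i, x_j) ≤ d}
    """
    n = pattern.n
    if n < 2:
        raise ValueError("k_net requires at least two events")
    d = _offdiag(pairwise_network_distances(pattern))
    scale = pattern.network.total_length / (n * (n - 1))
    values = scale * _accumulate(grid, d, np.ones_like(d))
    return SummaryFunction(grid=grid, values=values, kind="Knet")


def _check_rmax(pattern: NetworkPointPattern, grid: DistanceGrid) -> None:
    r = circumradius(pattern.network)
    if grid.r_max > r * (1 + _R_TOL) + _R_TOL:
        raise ValueError(
            f"grid r_max {grid.r_max:.6g} exceeds the circumradius {r:.6g}; "
            "the corrected K functions are defined only for d ≤ R")


def k_corrected(pattern: NetworkPointPattern, grid: DistanceGrid) -> SummaryFunction:
    """Geometrically corrected network K function::

        K̂_L(d) = |L| / (n(n−1)) · Σ_i Σ_{j≠i} 1{d_ij ≤ d} / m(x_i, d_ij)

    valid for 0 ≤ d ≤ R.  Under a homogeneous Poisson process on the network
    K_L(d) = d, independent of the network geometry.
    """
    n = pattern.n
    if n < 2:
        raise ValueError("k_corrected requires at least two events")
    _check_rmax(pattern, grid)
    dists = pairwise_network_distances(pattern)
    m = _pair_m_counts(pattern, dists)
    if np.any(m == 0):
        raise RuntimeError("internal error: m(x_i, d_ij) = 0 for a realized "
                           "inter-event distance")  # impossible for d ≤ ecc(x_i)
    d = _offdiag(dists)
    w = 1.0 / _offdiag(m)
    scale = pattern.network.total_length / (n * (n - 1))
    values = scale * _accumulate(grid, d, w)
    return SummaryFunction(grid=grid, values=values, kind="KL",
                           theoretical=grid.values.copy())


def k_inhom(pattern: NetworkPointPattern, intensity_at_events,
            grid: DistanceGrid) -> SummaryFunction:
    """Inhomogeneous geometrically corrected network K function::

        K̂_LI(d) = (Σ_i 1/λ̂(x_i))⁻¹ ·
                   Σ_i Σ_{j≠i} 1{d_ij ≤ d} / (λ̂(x_i) λ̂(x_j) m(x_i, d_ij))

    ``intensity_at_events`` gives λ̂(x_i) (events/μm) per event; all values
    must be strictly positive.
    """
    n = pattern.n
    if n < 2:
        raise ValueError("k_inhom requires at least two events")
    lam = np.asarray(intensity_at_events, dtype=float)
    if lam.shape != (n,):
        raise ValueError("intensity_at_events must have one value per event")
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("event intensities must be positive and finite")
    _check_rmax(pattern, grid)
    dists = pairwise_network_distances(pattern)
    m = _pair_m_counts(pattern, dists)
    if np.any(m == 0):
        raise RuntimeError("internal error: m(x_i, d_ij) = 0 for a realized "
                           "inter-event distance")
    wmat = 1.0 / (lam[:, None] * lam[None, :] * m)
    d = _offdiag(dists)
    w = _offdiag(wmat)
    scale = 1.0 / np.sum(1.0 / lam)
    values = scale * _accumulate(grid, d, w)
    return SummaryFunction(grid=grid, values=values, kind="KLI",
                           theoretical=grid.values.copy())
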