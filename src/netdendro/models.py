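"""Poisson point-process models on networks and synthetic data generation.

Simulation of homogeneous (CSR) and inhomogeneous Poisson processes on a
linear network, maximum-likelihood fitting of the log-quadratic intensity
model λ(u) = exp(θ0 + θ1·d(u) + θ2·d(u)²) with d the distance to the tree
root, and generators for synthetic dendritic trees and replicated grouped
patterns emulating pyramidal-cell morphologies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import (LinearNetwork3D, NetworkError, NetworkLocation,
                      build_network, distance_to_root)
from .intensity import NetworkPointPattern, _covariate_on_segments


class FitError(RuntimeError):
    """Raised when the intensity model fit fails to converge; carries the
    optimizer trajectory in ``trajectory``."""

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class LogQuadraticModel:
    """Log-quadratic intensity in the distance-to-root covariate d(u)::

        λ(u) = exp(θ0 + θ1·d(u) + θ2·d(u)²)

    θ0 is log(events/μm); θ1 per μm; θ2 per μm².  ``vcov`` (3×3, optional)
    is the inverse observed Fisher information from the fit.
    """

    theta0: float
    theta1: float
    theta2: float
    covariate: str = "distance_to_root"
    vcov: np.ndarray | None = field(default=None, repr=False)
    loglik: float | None = None

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.theta0, self.theta1, self.theta2])

    def standard_errors(self) -> np.ndarray:
        if self.vcov is None:
            raise ValueError("model has no variance estimate (not fitted)")
        return np.sqrt(np.diag(self.vcov))

    def intensity(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.exp(self.theta0 + self.theta1 * d + self.theta2 * d * d)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ----------------------------------------------------------------------
# simulation

def simulate_csr(net: LinearNetwork3D, lam: float | None = None,
                 fixed_n: int | None = None, seed=None) -> NetworkPointPattern:
    """Simulate complete spatial randomness (homogeneous Poisson) on ``net``.

    Either ``lam`` (events/μm; the event count is Poisson(λ·|L|)) or
    ``fixed_n`` (a binomial process with exactly that many events) must be
    given.  Locations are uniform by arc length: a segment is chosen with
    probability proportional to its length and the offset is uniform.
    """
    rng = _rng(seed)
    if (lam is None) == (fixed_n is None):
        raise ValueError("specify exactly one of lam or fixed_n")
    if lam is not None:
        if lam < 0:
            raise ValueError("intensity must be nonnegative")
        n = int(rng.poisson(lam * net.total_length))
    else:
        if fixed_n < 0:
            raise ValueError("fixed_n must be nonnegative")
        n = int(fixed_n)
    probs = net.lengths / net.total_length
    segs = rng.choice(net.n_segments, size=n, p=probs)
    offs = rng.uniform(0.0, net.lengths[segs]) if n else np.empty(0)
    events = [NetworkLocation(int(s), float(o)) for s, o in zip(segs, offs)]
    return NetworkPointPattern(net, events)


def _lambda_max(net: LinearNetwork3D, model: LogQuadraticModel) -> float:
    """Exact maximum of the log-quadratic intensity over the network.

    The covariate d(u) is piecewise linear along each segment, so λ is
    maximized either at a piece endpoint or, when θ2 < 0, at the quadratic's
    vertex d* = −θ1/(2θ2) if it falls inside the piece's covariate range.
    """
    t0, t1, t2 = model.theta0, model.theta1, model.theta2
    candidates = []
    for _, offs, vals in _covariate_on_segments(net):
        for c0, c1 in zip(vals[:-1], vals[1:]):
            lo, hi = min(c0, c1), max(c0, c1)
            candidates.extend([lo, hi])
            if t2 < 0:
                dstar = -t1 / (2 * t2)
                if lo <= dstar <= hi:
                    candidates.append(dstar)
    z = np.asarray(candidates)
    lam_max = float(np.exp(t0 + t1 * z + t2 * z * z).max())
    if not np.isfinite(lam_max):
        raise ValueError("log-quadratic intensity is unbounded on this network")
    return lam_max


def simulate_inhom(net: LinearNetwork3D, model: LogQuadraticModel,
                   seed=None) -> NetworkPointPattern:
    """Simulate an inhomogeneous Poisson process with log-quadratic intensity
    by Lewis–Shedler thinning: a CSR pattern at the exact dominating rate
    λ_max is thinned, retaining each point with probability λ(u)/λ_max."""
    if net.root is None:
        raise NetworkError("network root is not set")
    if not np.all(np.isfinite(model.theta)):
        raise ValueError("model parameters must be finite")
    rng = _rng(seed)
    lam_max = _lambda_max(net, model)
    dominating = simulate_csr(net, lam=lam_max, seed=rng)
    if dominating.n == 0:
        return dominating
    d = np.asarray(distance_to_root(net, dominating.events))
    keep = rng.uniform(size=dominating.n) < model.intensity(d) / lam_max
    events = [e for e, k in zip(dominating.events, keep) if k]
    return NetworkPointPattern(net, events)


# ----------------------------------------------------------------------
# fitting

def _quadrature_nodes(net: LinearNetwork3D, max_step: float = 1.0):
    """Trapezoidal quadrature nodes over the network in the distance-to-root
    covariate: returns (z, w) with ∫_L f(d(u)) du ≈ Σ w_k f(z_k).  Step per
    segment is ≤ min(max_step, length/10)."""
    zs, ws = [], []
    for _, offs, vals in _covariate_on_segments(net):
        for (o0, o1, c0, c1) in zip(offs[:-1], offs[1:], vals[:-1], vals[1:]):
            seg_len = o1 - o0
            if seg_len <= 0:
                continue
            step = min(max_step, seg_len / 10.0)
            k = max(int(np.ceil(seg_len / step)), 1)
            frac = np.linspace(0.0, 1.0, k + 1)
            zs.append(c0 + frac * (c1 - c0))
            w = np.full(k + 1, seg_len / k)
            w[[0, -1]] /= 2.0
            ws.append(w)
    return np.concatenate(zs), np.concatenate(ws)


def fit_log_quadratic(pattern: NetworkPointPattern, max_step: float = 1.0,
                      grad_tol: float = 1e-8, max_iter: int = 200) -> LogQuadraticModel:
    """Maximum-likelihood fit of the log-quadratic intensity model.

    Maximizes the inhomogeneous Poisson process log-likelihood

        ℓ(θ) = Σ_i log λ_θ(x_i) − ∫_L λ_θ(u) du

    with the integral computed by per-segment trapezoidal quadrature.  The
    optimizer is a damped Newton iteration with analytic gradient and
    Hessian, started at the homogeneous solution (log(n/|L|), 0, 0); the
    covariate is standardized internally for conditioning.  Convergence when
    the (scaled) gradient norm drops below ``grad_tol``.
    """
    n = pattern.n
    if n < 10:
        warnings.warn(f"only {n} events: the quadratic intensity fit is "
                      "unstable below 10 events")
    if n == 0:
        raise ValueError("cannot fit an intensity model to an empty pattern")
    z_ev = pattern.covariates()
    zq, wq = _quadrature_nodes(pattern.network, max_step=max_step)
    scale = max(float(zq.max()), 1.0)

    def design(z):
        zs = z / scale
        return np.column_stack([np.ones_like(zs), zs, zs * zs])

    X_ev = design(z_ev)
    X_q = design(zq)
    t_obs = X_ev.sum(axis=0)

    theta = np.array([np.log(n / pattern.network.total_length), 0.0, 0.0])
    trajectory = [theta.copy()]

    def loglik_parts(th):
        lam_q = np.exp(X_q @ th)
        ll = float((X_ev @ th).sum() - wq @ lam_q)
        return ll, lam_q

    ll, lam_q = loglik_parts(theta)
    for _ in range(max_iter):
        grad = t_obs - X_q.T @ (wq * lam_q)
        if np.linalg.norm(grad) < grad_tol:
            break
        hess = -(X_q.T * (wq * lam_q)) @ X_q
        try:
            step_dir = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError:
            raise FitError("singular Hessian in Newton iteration", trajectory)
        # damped Newton: halve until the likelihood does not decrease
        t = 1.0
        for _ in range(40):
            cand = theta + t * step_dir
            ll_new, lam_new = loglik_parts(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            t /= 2.0
        else:
            raise FitError("line search failed", trajectory)
        theta, ll, lam_q = cand, ll_new, lam_new
        trajectory.append(theta.copy())
    else:
        raise FitError(f"Newton iteration did not converge in {max_iter} "
                       "iterations", trajectory)

    hess = -(X_q.T * (wq * lam_q)) @ X_q
    vcov_scaled = np.linalg.inv(-hess)
    # undo the covariate standardization: theta_j = theta_scaled_j / scale**j
    s = np.array([1.0, scale, scale * scale])
    theta_nat = theta / s
    vcov = vcov_scaled / np.outer(s, s)
    return LogQuadraticModel(theta0=float(theta_nat[0]), theta1=float(theta_nat[1]),
                             theta2=float(theta_nat[2]), vcov=vcov, loglik=ll)


def log_quadratic_loglik(pattern: NetworkPointPattern, model: LogQuadraticModel,
                         max_step: float = 1.0) -> float:
    """Poisson process log-likelihood of ``model`` for ``pattern`` (same
    quadrature as :func:`fit_log_quadratic`)."""
    z_ev = pattern.covariates()
    zq, wq = _quadrature_nodes(pattern.network, max_step=max_step)
    lam_ev = model.intensity(z_ev)
    return float(np.sum(np.log(lam_ev)) - wq @ model.intensity(zq))


# ----------------------------------------------------------------------
# synthetic dendrites

@dataclass
class SyntheticTreeSpec:
    """Parameters of the synthetic dendrite generator.

    Defaults emulate the reconstructed human pyramidal-cell dendrites:
    total length 327–3255 μm, 2–23 branching points (roughly one bifurcation
    per 140 μm of dendrite), an initial unbranched trunk, ~2 μm tortuous
    growth steps and moderate bifurcation angles.
    """

    length_range: tuple[float, float] = (400.0, 3000.0)
    branch_point_range: tuple[int, int] = (2, 23)
    branch_rate: float = 1.0 / 140.0  # bifurcations per μm of total length
    trunk_length_range: tuple[float, float] = (20.0, 80.0)
    step: float = 2.0                 # tortuosity step, μm
    angle_spread: float = 12.0        # per-step direction jitter, degrees
    branch_angle: float = 40.0        # angle between sibling branches, degrees

    def validate(self) -> None:
        if self.length_range[0] <= 0 or self.length_range[1] < self.length_range[0]:
            raise ValueError("invalid length_range")
        if self.step <= 0 or self.branch_rate < 0:
            raise ValueError("step and branch_rate must be positive")
        if self.trunk_length_range[0] < 0:
            raise ValueError("trunk length must be nonnegative")
        if self.length_range[0] <= self.trunk_length_range[1]:
            raise ValueError("length_range must exceed the trunk length")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perp_unit(d: np.ndarray, rng) -> np.ndarray:
    v = rng.normal(size=3)
    v -= (v @ d) * d
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        return _perp_unit(d, rng)
    return v / nv


def generate_dendrite(spec: SyntheticTreeSpec | None = None,
                      seed=None) -> LinearNetwork3D:
    """Grow a synthetic rooted 3D dendritic tree by a branching random walk.

    Active tips advance in polyline steps of ``spec.step`` μm with the
    direction jittered by ``angle_spread`` degrees per step.  A target total
    length is drawn uniformly from ``length_range`` and a bifurcation count
    from Poisson(branch_rate · length), truncated to ``branch_point_range``;
    bifurcations occur at arc-length positions uniform over the growth and
    split the growing tip into two branches diverging by ``branch_angle``.
    """
    spec = spec or SyntheticTreeSpec()
    spec.validate()
    rng = _rng(seed)

    target_len = rng.uniform(*spec.length_range)
    trunk = rng.uniform(*spec.trunk_length_range)
    lo_bp, hi_bp = spec.branch_point_range
    n_branch = int(np.clip(rng.poisson(spec.branch_rate * target_len), lo_bp, hi_bp))
    branch_at = np.sort(rng.uniform(trunk, 0.95 * target_len, size=n_branch))

    jitter = np.tan(np.radians(spec.angle_spread))
    half = np.tan(np.radians(spec.branch_angle / 2.0))

    verts = [np.zeros(3)]
    edges: list[tuple[int, int]] = []
    # each tip: (vertex index, direction)
    tips = [(0, _random_unit(rng))]
    total = 0.0
    next_branch = 0
    while total < target_len:
        k = rng.integers(len(tips))
        vi, d = tips[k]
        d = _unit(d + jitter * rng.normal(size=3))
        new_pos = verts[vi] + spec.step * d
        verts.append(new_pos)
        nv = len(verts) - 1
        edges.append((vi, nv))
        total += spec.step
        if next_branch < n_branch and total >= branch_at[next_branch]:
            next_branch += 1
            u = _perp_unit(d, rng)
            d1 = _unit(d + half * u)
            d2 = _unit(d - half * u)
            tips[k] = (nv, d1)
            tips.append((nv, d2))
        else:
            tips[k] = (nv, d)
    if total <= 0:
        raise ValueError("tree specification yields a zero-length tree")
    return build_network(np.asarray(verts), edges, root_vertex=0)


@dataclass
class GroupedPatterns:
    """g groups of replicated point patterns, each on its own network."""

    groups: list[list[NetworkPointPattern]]

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if any(len(g) < 1 for g in self.groups):
            raise ValueError("every group needs at least one pattern")

    @property
    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    def flat(self) -> list[NetworkPointPattern]:
        return [p for g in self.groups for p in g]


def generate_replicated_groups(g: int, sizes, models, spec=None,
                               seed=None) -> GroupedPatterns:
    """Generate g groups of replicated patterns on independent synthetic trees.

    Group ``i`` receives ``sizes[i]`` patterns, each simulated from
    ``models[i]`` (a :class:`LogQuadraticModel`) on a fresh tree drawn from
    ``spec``.  Deterministic for a given seed.
    """
    if not (g == len(sizes) == len(models)):
        raise ValueError("g, sizes and models must have matching lengths")
    spec = spec or SyntheticTreeSpec()
    rng = _rng(seed)
    groups = []
    for size, model in zip(sizes, models):
        pats = []
        for _ in range(size):
            net = generate_dendrite(spec, seed=rng)
            pats.append(simulate_inhom(net, model, seed=rng))
        groups.append(pats)
    return GroupedPatterns(groups=groups)
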