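"""Monte Carlo and permutation inference for network point patterns.

Two procedures:

* a global envelope test for a single pattern against a Poisson null model
  (homogeneous or log-quadratic), with a constant-width band built from
  ``n_sim`` simulations — 19 simulations give the conventional Monte Carlo
  significance level 1/(1+19) = 0.05;
* the studentized permutation test for replicated grouped patterns, which
  compares group mean summary functions with the H statistic and computes a
  p-value by permuting pattern-to-group labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import circumradius
from .intensity import NetworkPointPattern, uniform_intensity
from .kfunctions import DistanceGrid, SummaryFunction, k_corrected, k_inhom
from .models import (GroupedPatterns, LogQuadraticModel, fit_log_quadratic,
                     simulate_csr, simulate_inhom, _rng)


@dataclass
class EnvelopeResult:
    """Global envelope test output.

    The band has constant width 2·w_max around the theoretical Poisson curve
    K_L(d) = d, where w_max is the largest absolute deviation of any
    simulated summary from the theoretical curve; the model is rejected when
    the empirical summary leaves the band anywhere on the grid.
    """

    grid: DistanceGrid
    empirical: np.ndarray
    theoretical: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    w_max: float
    n_sim: int
    rejected: bool

    @property
    def nominal_level(self) -> float:
        return 1.0 / (1.0 + self.n_sim)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"d": self.grid.values, "value": self.empirical,
                             "theoretical": self.theoretical,
                             "lower": self.lower, "upper": self.upper})


@dataclass
class PermutationTestResult:
    """Studentized permutation test output."""

    h_observed: float
    h_permuted: np.ndarray
    p_value: float
    n_perm: int
    interval: tuple[float, float]


def _summary_for(pattern: NetworkPointPattern, summary: str,
                 grid: DistanceGrid) -> SummaryFunction:
    if summary == "KL":
        return k_corrected(pattern, grid)
    if summary == "KLI":
        model = fit_log_quadratic(pattern)
        lam = model.intensity(pattern.covariates())
        return k_inhom(pattern, lam, grid)
    raise ValueError(f"unknown summary {summary!r}; use 'KL' or 'KLI'")


def global_envelope_test(pattern: NetworkPointPattern, null_model=None,
                         summary: str = "KL", n_sim: int = 19,
                         grid: DistanceGrid | None = None,
                         seed=None) -> EnvelopeResult:
    """Global envelope Monte Carlo goodness-of-fit test for one pattern.

    ``null_model`` may be a CSR rate (events/μm), a
    :class:`LogQuadraticModel`, or None, in which case CSR at λ̂ = n/|L| is
    used for ``summary='KL'`` and a log-quadratic model fitted to the pattern
    for ``summary='KLI'``.  For the inhomogeneous summary the intensity is
    re-fitted on every simulated pattern, so the envelope accounts for
    intensity estimation.
    """
    if pattern.n < 2:
        raise ValueError("envelope test requires at least two events")
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    net = pattern.network
    if grid is None:
        from .kfunctions import default_grid

        grid = default_grid(net)
    rng = _rng(seed)
    if null_model is None:
        if summary == "KLI":
            null_model = fit_log_quadratic(pattern)
        else:
            null_model = uniform_intensity(pattern)

    def simulate():
        for _ in range(1000):  # reject degenerate (<2 events) realizations
            if isinstance(null_model, LogQuadraticModel):
                sim = simulate_inhom(net, null_model, seed=rng)
            else:
                sim = simulate_csr(net, lam=float(null_model), seed=rng)
            if sim.n >= 2:
                return sim
        raise RuntimeError("null model almost never yields 2+ events")

    empirical = _summary_for(pattern, summary, grid).values
    theoretical = grid.values.copy()
    w_max = 0.0
    for _ in range(n_sim):
        sim_vals = _summary_for(simulate(), summary, grid).values
        w_max = max(w_max, float(np.max(np.abs(sim_vals - theoretical))))
    lower = theoretical - w_max
    upper = theoretical + w_max
    rejected = bool(np.any((empirical < lower) | (empirical > upper)))
    return EnvelopeResult(grid=grid, empirical=empirical, theoretical=theoretical,
                          lower=lower, upper=upper, w_max=w_max, n_sim=n_sim,
                          rejected=rejected)


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    w[:-1] += np.diff(x) / 2.0
    w[1:] += np.diff(x) / 2.0
    return w


def h_statistic(summaries: list[list[SummaryFunction]] | list[list[np.ndarray]],
                d0: float, d1: float,
                grid: np.ndarray | None = None) -> float:
    """Studentized between-group statistic for replicated summary functions::

        H = Σ_{i<j} ∫_{d0}^{d1} (T̄_i(d) − T̄_j(d))² / (s̄_i²/m_i + s̄_j²/m_j) dd

    where T̄_i is the mean summary of group i and s̄_i² its within-group
    variance averaged over [d0, d1].  Integrals use the trapezoidal rule on
    the common grid.  A pair with zero denominator contributes 0 when its
    numerator integral is also 0, and +inf otherwise.

    ``summaries`` holds, per group, the member summaries either as
    :class:`SummaryFunction` objects on a common grid or as plain value
    arrays (then ``grid`` must be given).
    """
    if d1 <= d0:
        raise ValueError("need d0 < d1")
    groups = []
    common = grid
    for gsum in summaries:
        if len(gsum) == 0:
            raise ValueError("every group must be nonempty")
        vals = []
        for s in gsum:
            if isinstance(s, SummaryFunction):
                if common is None:
                    common = s.grid.values
                elif len(common) != len(s.grid.values) or not np.allclose(
                        common, s.grid.values):
                    raise ValueError("summaries must share a common grid")
                vals.append(s.values)
            else:
                vals.append(np.asarray(s, dtype=float))
        groups.append(np.vstack(vals))
    if common is None:
        raise ValueError("grid required when passing plain arrays")
    common = np.asarray(common, dtype=float)
    tol = 1e-9 * max(1.0, d1)
    if common[0] > d0 + tol or common[-1] < d1 - tol:
        raise ValueError(f"common grid [{common[0]:.6g}, {common[-1]:.6g}] does "
                         f"not cover [{d0}, {d1}]")
    mask = (common >= d0 - tol) & (common <= d1 + tol)
    x = common[mask]
    w = _trapezoid_weights(x)

    means, svars, sizes = [], [], []
    for vals in groups:
        m_i = vals.shape[0]
        if m_i < 2:
            raise ValueError("within-group variance undefined for a group of size 1")
        v = vals[:, mask]
        mean = v.mean(axis=0)
        var_d = v.var(axis=0, ddof=1)
        svars.append(float(w @ var_d) / (d1 - d0))
        means.append(mean)
        sizes.append(m_i)

    h = 0.0
    g = len(groups)
    for i in range(g):
        for j in range(i + 1, g):
            denom = svars[i] / sizes[i] + svars[j] / sizes[j]
            numer = float(w @ (means[i] - means[j]) ** 2)
            if denom == 0.0:
                if numer == 0.0:
                    continue
                return float("inf")
            h += numer / denom
    return float(h)


def studentized_permutation_test(groups: GroupedPatterns, summary: str = "KL",
                                 d0: float = 0.0, d1: float | None = None,
                                 n_perm: int = 1000, seed=None,
                                 grid_points: int = 256) -> PermutationTestResult:
    """Studentized permutation test for replicated grouped patterns.

    Each pattern's summary (K̂_L, or K̂_LI with its own fitted log-quadratic
    intensity) is computed on its own network over a common distance grid of
    ``grid_points`` equispaced values on [d0, d1].  By default d1 is 2% below
    the smallest circumradius over all networks, the largest range on which
    the corrected summaries of every pattern are valid.  The p-value ranks
    the observed H among ``n_perm`` random relabelings of patterns to groups
    (group sizes preserved): p = (1 + #{H* ≥ H_obs}) / (1 + n_perm), never 0.
    """
    sizes = groups.sizes
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if any(m < 2 for m in sizes):
        raise ValueError("every group needs at least two patterns "
                         "(within-group variance undefined otherwise)")
    if any(m < 3 for m in sizes):
        warnings.warn("each group should contain at least three patterns for "
                      "reasonably precise within-group variance estimates")
    flat = groups.flat()
    radii = np.array([circumradius(p.network) for p in flat])
    if d1 is None:
        d1 = 0.98 * float(radii.min())
    bad = np.nonzero(radii < d1 - 1e-9)[0]
    if len(bad):
        raise ValueError(
            f"d1 = {d1:.6g} exceeds the circumradius of pattern(s) "
            f"{list(bad)} (R = {[round(float(radii[i]), 2) for i in bad]}); "
            "shorten d1 or exclude those networks")
    if d1 <= d0:
        raise ValueError("need d0 < d1 (check circumradii)")

    grid = DistanceGrid(np.linspace(d0, d1, grid_points))
    values = np.vstack([_summary_for(p, summary, grid).values for p in flat])

    labels = np.concatenate([np.full(m, i) for i, m in enumerate(sizes)])

    def h_for(lab):
        byg = [values[lab == i] for i in range(len(sizes))]
        return h_statistic([list(v) for v in byg], d0, d1, grid=grid.values)

    h_obs = h_for(labels)
    rng = _rng(seed)
    h_perm = np.empty(n_perm)
    for k in range(n_perm):
        h_perm[k] = h_for(labels[rng.permutation(len(labels))])
    p = (1.0 + np.sum(h_perm >= h_obs)) / (1.0 + n_perm)
    return PermutationTestResult(h_observed=float(h_obs), h_permuted=h_perm,
                                 p_value=float(p), n_perm=n_perm,
                                 interval=(float(d0), float(d1)))
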