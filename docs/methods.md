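# Methods

This note records the models implemented in `netdendro`, the numerical
choices behind them, and what the synthetic-data generator does and does not
emulate.

## Networks and the geodesic metric

A network is a finite union of straight segments in 3D whose graph is
connected and acyclic — a geodesic tree.  Construction (`build_network`)
rejects cycles, disconnection and zero-length segments outright rather than
half-supporting them: on a disconnected network shortest-path distances are
infinite and every summary below is undefined, and dendrites are trees.
Segment arc lengths are always recomputed from the vertex coordinates, so
the invariant "length = Euclidean distance of endpoints" holds by
construction.  All coordinates and lengths are micrometres; there is no unit
layer.

On-network locations are (segment, offset) pairs.  Locations within 1e-9 μm
of a vertex are canonicalized to a single representation (lowest incident
segment id), so equality is well defined across the segments that meet at a
vertex.

Distances use a cached all-pairs vertex distance matrix (Dijkstra on the
segment graph).  On a tree, the distance from an interior location to any
vertex is the minimum over its two segment endpoints of offset-plus-vertex
distance, and within a single segment the direct arc is the geodesic; this
closed form is what the package computes, and the test suite checks it
against Dijkstra on graphs with temporary vertices inserted at the query
locations.

**Exact-distance count m(u, t).**  `m(u, t)` is the number of network
locations at exactly distance `t` from `u`.  On a tree every segment not
carrying `u` is entered through exactly one endpoint, so its interior covers
the open distance interval (d_enter, d_enter + length) exactly once; the
carrying segment contributes its two half-intervals.  `m(u, t)` is the
number of such open intervals containing `t` plus the number of vertices at
distance exactly `t`; a vertex counts once regardless of how many branches
meet there (set cardinality), a choice that matters only on a measure-zero
set of distances.  `m(u, 0) = 1`.  Exact-equality comparisons use a 1e-9 μm
tolerance; inter-event distances and vertex distances are produced by the
same arithmetic, so the tolerance is reliable in practice.

**Circumradius.**  `R = sup{t : m(u, t) > 0 for all u}` equals the radius of
the geodesic tree, i.e. half its diameter.  The diameter is found by a
double sweep over vertices (the farthest point from any location on a tree
is a leaf), which is exact — no numerical eccentricity minimization.

**Snapping.**  Spine attachment coordinates rarely sit exactly on the
reconstructed axis.  `snap_to_network` orthogonally projects a 3D point onto
every segment and takes the closest, breaking exact ties by lowest segment
id then lowest offset, and refuses points farther than a caller-supplied
limit.  Nearest-point projection is this package's choice of attachment
rule; reconstruction pipelines do not standardize one.

## Intensity

`uniform_intensity` is `n/|L|`.  The covariate of interest is the distance
to the tree root (the soma); along each segment it is piecewise linear with
slope ±1 per μm of arc length, which makes two things exact rather than
discretized: the length-weighted null CDF `F0` used by the CDF test, and the
per-segment handling of the kernel estimator's denominator.

`rho_of_covariate` estimates `ρ` in `λ(u) = ρ(Z(u))` as a ratio: a Gaussian
kernel sum over event covariate values divided by the kernel-smoothed length
density `∫_L κ_h(z − Z(u)) du`, the latter by per-segment trapezoidal
quadrature with step ≤ min(1 μm, h/8, length/10) — at h/8 the trapezoid
error is well below 0.1% of the integrand.  The default bandwidth is
Scott's rule, `h = σ̂ n^(−1/5)`, on the event covariate values; no
authoritative bandwidth exists for this application, so the default is the
standard density-estimation choice and is reported in the result object.
The API accepts any per-location covariate function, but only
distance-to-root is exercised by the tests.

The CDF (Kolmogorov–Smirnov) test compares the empirical covariate CDF at
events with `F0`, evaluating the sup at event values and their left limits;
the p-value uses the asymptotic one-sample KS distribution.  Duplicate
events (possible reconstruction artifacts) are kept with multiplicity and
flagged with a warning.

## K functions

All three estimators are cumulative sums of nonnegative pair weights and are
evaluated exactly at arbitrary grid points (no binning of distances: each
pair contributes at the first grid value ≥ its distance, so grid evaluation
equals exact evaluation at the grid points).  Tied inter-event distances sum
their weights; events at vertices follow the vertex rule of `m`.  The
corrected versions require the grid to stay within the circumradius and
default to 512 equispaced values on [0, 0.98·R], 2% below the circumradius.
Inter-event distances are computed once per pattern (vectorized over the
vertex-distance matrix) and `m(x_i, d_ij)` is evaluated for all ordered
pairs from per-event sorted interval tables.  `m ≥ 1` is guaranteed for any
realized inter-event distance (it cannot exceed the eccentricity of the
source event); the implementation still guards this invariant.

## Poisson models

CSR simulation picks each event's segment with probability proportional to
length and a uniform offset; the count is Poisson(λ|L|), or fixed for
binomial (conditional) simulation.  Inhomogeneous simulation uses
Lewis–Shedler thinning with the dominating rate computed exactly: on each
segment the covariate range is known, and the log-quadratic exponent is
maximized at a range endpoint or (when θ2 < 0) at the parabola vertex.

`fit_log_quadratic` maximizes the continuous Poisson process log-likelihood
`ℓ(θ) = Σ_i log λ_θ(x_i) − ∫_L λ_θ(u) du` directly, rather than through a
lattice/GLM approximation: the integral uses per-segment trapezoidal
quadrature with step ≤ min(1 μm, length/10), and the optimizer is a damped
Newton iteration with analytic gradient and Hessian (the likelihood is
strictly concave), started at the homogeneous fit (log(n/|L|), 0, 0).  For
conditioning, the covariate is standardized internally by its maximum (z,
z² span ~1e2, ~1e5 μm-scales otherwise); convergence is declared when the
gradient norm in the scaled coordinates drops below 1e-8, and failure after
200 iterations raises an error carrying the iterate trajectory.  The
reported variance is the inverse observed Fisher information; tests confirm
3-standard-error coverage of all three parameters in ≥95% of simulations at
n ≈ 2000.  Below 10 events the quadratic is unstable; the fit warns and
proceeds.

## Envelope and permutation inference

The global envelope test simulates `n_sim` patterns from the null model on
the observed network, computes the chosen summary for each, sets `w_max` to
the largest absolute deviation of any simulated summary from the Poisson
reference `K_L(d) = d`, and rejects when the empirical summary leaves the
constant-width band `d ± w_max`.  With 19 simulations the test has exact
Monte Carlo level 1/(1+19) = 0.05.  For the inhomogeneous summary the
log-quadratic intensity is **re-fitted on every simulated pattern**, so the
band reflects intensity-estimation variability; whether to refit was a
genuinely open design point, and refitting is the conservative choice.

The studentized permutation test computes each pattern's summary on its own
network over a common grid of 256 equispaced distances on [d0, d1]
(computed directly at the common grid points — exact, so no interpolation
step is needed), with `d1` defaulting to 2% below the smallest circumradius
across the networks, the largest range on which every corrected summary is
valid; a `d1` beyond any pattern's circumradius is an error naming the
offending networks.  For the inhomogeneous summary each pattern uses its own
fitted log-quadratic intensity.  The statistic `H` integrates squared group
mean differences scaled by time-averaged within-group variances
(trapezoidal rule); a 0/0 pair contributes 0 and a nonzero/0 pair yields
+infinity, which still ranks correctly among permutations.  The p-value is
`(1 + #{H* ≥ H_obs}) / (1 + n_perm)` — the exact-test-valid convention that
can never return 0 — with group sizes preserved under relabeling and all
permutations drawn from one seeded generator.  Groups of fewer than three
patterns make the within-group variance imprecise; the test warns below
three and refuses below two.

## Synthetic data

`generate_dendrite` grows a rooted tree by a branching random walk: active
tips advance in 2 μm polyline steps with the direction jittered by ~12°
per step, an initial unbranched trunk of 20–80 μm, and bifurcations (40°
between siblings) at arc positions uniform over the growth.  The target
total length is drawn uniformly from 400–3000 μm and the bifurcation count
from Poisson(length/140) truncated to 2–23 — both ranges, and the ~one
bifurcation per 140 μm rate, taken from published descriptions of human
pyramidal-cell apical and basal dendrites.  The generator reproduces those
aggregate morphology statistics and a tree topology; it does **not** emulate
taper, diameter, tropism toward the pia, space-filling constraints or
3D self-avoidance, so a green test establishes correctness of the spatial
statistics on tree networks of realistic size and branching, not biological
realism of the trees themselves.  Replicated groups are built by drawing an
independent tree per pattern and simulating from a per-group intensity
model; all generators are reproducible from a single seed.

## Degenerate inputs and numerical edges

* Empty patterns: intensity 0; `rho`, `cdf_test`, K functions and the fit
  raise informative errors.
* Locations off the network, offsets beyond segment length, negative
  distances, nonpositive intensities and grids beyond the circumradius all
  raise `ValueError`/`NetworkError` with the offending quantity named.
* SWC ingestion collapses consecutive duplicate coordinates with a warning
  (zero-length segments are unrepresentable) and reports malformed lines by
  number; round-tripping a tree through SWC preserves lengths, circumradius
  and branch-point count to 1e-6.

## Known limitations

* Networks must be trees; cyclic networks (e.g. road networks) are out of
  scope — the closed-form distance and `m` computations rely on acyclicity.
* The kernel intensity estimator is the ratio estimator only; no adaptive or
  boundary-corrected variants.
* Only first-order inhomogeneity via the distance-to-root covariate is
  fitted; marked patterns (spine size or type) and non-Poisson models are
  not implemented.
* The CDF test p-value is asymptotic; for very small n a Monte Carlo
  p-value would be preferable.
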