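# netdendro

Spatial point-pattern analysis on **3D linear networks** — trees of line
segments embedded in space, with point events constrained to lie on them.
The motivating application is the distribution of **dendritic spines** along
the dendritic arborizations of pyramidal neurons: spines can only sit on the
dendritic shaft, so their spatial statistics must be computed with
shortest-path (geodesic) distances along the dendrite, not Euclidean
distances in space.  The package is aimed at neuroanatomists and spatial
statisticians working with reconstructed neuron morphologies (SWC), but the
machinery applies to any point process on a 3D tree network.

## What it computes

Let `L` be a connected acyclic union of line segments with total length
`|L|`, and `x_1, …, x_n` events on it.  With `d_L` the shortest-path metric:

* **Intensity.** The homogeneous estimate `λ̂ = n/|L|`; a kernel estimate of
  `ρ` in `λ(u) = ρ(d_L(u))` where `d_L(u)` is the distance to the tree root
  (the soma); and a Kolmogorov–Smirnov *CDF test* of whether the intensity
  depends on that covariate, comparing the covariate distribution at events
  with its exact length-weighted distribution over the network.
* **Network K functions.**

      K̂_net(d) = |L|/(n(n−1)) Σ_i Σ_{j≠i} 1{d_L(x_i,x_j) ≤ d}
      K̂_L(d)   = |L|/(n(n−1)) Σ_i Σ_{j≠i} 1{d_L(x_i,x_j) ≤ d} / m(x_i, d_ij)
      K̂_LI(d)  = (Σ_i 1/λ̂(x_i))⁻¹ Σ_i Σ_{j≠i} 1{d_ij ≤ d} / (λ̂(x_i) λ̂(x_j) m(x_i, d_ij))

  where `m(u, t)` is the number of network points at exactly distance `t`
  from `u`.  The geometric correction by `1/m` makes `K_L` comparable across
  networks: under a homogeneous Poisson process `K_L(d) = d` for
  `0 ≤ d ≤ R`, with `R` the network circumradius.
* **Models.** Simulation of homogeneous (CSR) and inhomogeneous Poisson
  processes on the network (Lewis–Shedler thinning with an exact dominating
  rate), and maximum-likelihood fitting of the log-quadratic intensity
  `λ(u) = exp(θ0 + θ1 d(u) + θ2 d(u)²)`.
* **Inference.** Global envelope tests with constant-width bands from `n_sim`
  null simulations (19 simulations → level `1/(1+19) = 0.05`), and the
  **studentized permutation test** for `g` groups of replicated patterns,

      H = Σ_{i<j} ∫_{d0}^{d1} ( T̄_i(d) − T̄_j(d) )² / ( s̄_i²/m_i + s̄_j²/m_j ) dd

  with a p-value from ranking the observed `H` among random relabelings of
  patterns to groups.
* **Synthetic data.** A generator for rooted 3D dendrite-like trees (branching
  random walk calibrated to published human pyramidal-cell morphologies:
  total length ≈ 330–3250 μm, 2–23 branch points) and for replicated grouped
  patterns on them.

## Worked example

```python
import numpy as np
import netdendro as nd

rng = np.random.default_rng(1)
net = nd.generate_dendrite(seed=rng)                      # synthetic dendrite
model = nd.LogQuadraticModel(np.log(0.8), 0.012, -3e-5)   # rise-then-fall intensity
pattern = nd.simulate_inhom(net, model, seed=rng)

rec = nd.describe(net, pattern)
cdf = nd.cdf_test(pattern)
fit = nd.fit_log_quadratic(pattern)
env = nd.global_envelope_test(pattern, summary="KLI", n_sim=19,
                              grid=nd.default_grid(net, n_points=256), seed=rng)
```

Running this (it is the first half of `scripts/acceptance.py --seed 1`)
prints:

```
network: |L| = 1732.00 um, R = 410.00 um, 10 branch points
pattern: n = 1773, n/|L| = 1.02 events/um
rho(d): peak 2.448 events/um at d = 151.4 um (bandwidth 28.0 um)
CDF test: D = 0.3517, p = 7.11e-191
log-quadratic fit: theta = (-0.1174, 0.01073, -2.74e-05)
envelope (19 sims, level 0.05): w_max = 8.309, rejected = False
```

Reading it: the simulated dendrite is 1.7 mm long with an overall spine
density of 1.02 events/μm; the kernel estimate of `ρ` shows the density
rising to a peak ~150 μm from the root and falling off; the CDF test
overwhelmingly rejects intensity independence of distance-to-root; the fitted
log-quadratic parameters recover the generating values (log 0.8 ≈ −0.22,
0.012, −3·10⁻⁵) to within sampling error; and the 19-simulation global
envelope of `K̂_LI` retains the (true) inhomogeneous Poisson model.

A command-line interface mirrors the library:

```bash
netdendro simulate --seed 5 --lam 0.8 --out-prefix sim
netdendro describe --swc sim.swc --events sim_events.csv
netdendro kfun --swc sim.swc --events sim_events.csv --kind inhom --out k.csv
netdendro envelope --swc sim.swc --events sim_events.csv --nsim 19 --seed 1 --out env.csv
netdendro permtest --groups manifest.csv --nperm 1000 --seed 1
```

## Acceptance script

`scripts/acceptance.py` exercises the full pipeline from scratch — synthetic
dendrite generation, inhomogeneous simulation, descriptive statistics, kernel
intensity, CDF test, log-quadratic fit, a 19-simulation `K_LI` envelope test,
and a replicated two-group permutation test — and writes its JSON results
manifest:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`.
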