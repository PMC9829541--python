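# hypergeo

Analysis toolkit for testing whether a population of place cells
encodes space according to a latent **hyperbolic geometry**, and for
quantifying how that geometry grows with experience.

Hippocampal CA1 neurons fire in restricted place fields. If the
population implements a hierarchical, negatively curved
representation, the field sizes s follow a (sinh-truncated)
exponential law

    p(s) = ζ sinh(ζ(s_max − s)) / (cosh(ζ s_max) − 1)  ≈  ζ e^{−ζs},

whose exponent ζ is the curvature (inverse mean field size), and the
pairwise correlation structure of the spike trains matches that of
points sampled uniformly from a hyperbolic ball rather than from a
Euclidean box. `hypergeo` implements the complete chain needed to
test this on spike data, together with a synthetic-data generator so
that every stage is testable without recordings:

* `hypergeo.synth` — trajectories, Gaussian-tuning place-cell
  populations with exponential field-size statistics and gamma field
  counts, inhomogeneous-Poisson spikes, circular-shuffle controls.
* `hypergeo.correlation` — unbinned pairwise correlation
  `C_ij = max(N_ij, N_ji)/(τ_max r_i r_j T)` with rate-band and
  session-window filters.
* `hypergeo.topology` — Betti curves β₁–β₃ of the clique-complex
  order filtration (from-scratch GF(2) persistence engine, exact on
  the full edge-density grid, invariant to monotone transforms of the
  similarities).
* `hypergeo.geometry` / `hypergeo.geomfit` — sampling from hyperbolic
  (native model) and Euclidean geometries, noisy distance matrices,
  ensemble p-values, the R_max grid search by β₁/β₂ p-value product,
  neuron bootstrap, dimension χ², and the undersampling-bias
  simulation.
* `hypergeo.fields` / `hypergeo.curvature` — rate maps, place-field
  detection (1-D/2-D), spatial information, segment entropy and
  temporal familiarity; the truncated-window Bayesian curvature
  estimator, information-acquisition curve
  `I = log(1 + T/t₀) + (T/t₀)log(1 + t₀/T)`, radius-growth fits, and
  the exponential-to-log-normal detection-bias simulation.
* `hypergeo.decode` — Bayesian maximum-likelihood position decoding
  and the spike-efficiency exponent c.
* `hypergeo.fisher` — Fisher information `I(s) = Σ ∇f ∇fᵀ / f` of
  Gaussian-tuning Poisson populations; exponential vs uniform vs
  log-normal field-size comparisons; optimal-radius-vs-network-size
  sweeps.
* `hypergeo.pipeline` — session CSV/HDF5 I/O and a seeded end-to-end
  pipeline.

The package is a library: import it, or run the narrative scripts in
`examples/` (one per capability). See `docs/methods.md` for the
models, defaults and numerical choices.

## Worked example

Estimate the radius of a known latent geometry
(`examples/03_fit_hyperbolic_radius.py`): sample 50 points from a 3-D
hyperbolic ball of radius 10, corrupt the distances with 5%
multiplicative noise, and search the radius grid by comparing Betti
curves against model ensembles:

```text
true radius             : 10.0
estimated radius        : 11.0
best p-value product    : 0.473
p-values at the optimum : {'int beta_1': 0.68, 'int beta_2': 0.84} {'L1 beta_1': 0.9, 'L1 beta_2': 0.92}
```

The four p-values say the observed integrated Betti values and curve
shapes sit comfortably inside the model ensemble at R ≈ 11; their
product, maximized over the grid, is the radius estimate (single-draw
estimates scatter by ±2–3; medians over draws recover the truth).

The same machinery applied to a fully synthetic spike session
(`examples/07_full_pipeline.py`) — 50 cells, 20 minutes in a 180-cm
box — prints:

```text
spikes simulated        : 44613
eligible neurons        : 50
integrated Betti values : {1: 3.77, 2: 2.85}
fitted hyperbolic radius: 14.0
p-value products on grid: [0.0, 0.0, 0.0, 0.012, 0.185, 0.028]
curvature from fields   : 0.020 /cm (51 fields)
```

and the Fisher-information comparison
(`examples/06_fisher_information.py`) shows why exponential field
sizes are the information-optimal choice:

```text
size distribution       : mean det(I)^0.5 (1000 iterations)
  exponential           :      57128 +- 2766
  uniform               :      43189 +- 3832
  lognormal             :      34075 +- 555
```

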