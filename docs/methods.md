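# Methods

This note documents the models, estimators, numerical choices and
known limitations of `hypergeo`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scientific setting

Place cells in hippocampal CA1 fire in restricted regions of an
environment. If the population implements a latent hyperbolic
representation — a negatively curved space whose volume grows
exponentially with radius — three quantitative signatures follow:

1. **Field-size law.** One-dimensional place-field sizes follow the
   sinh-truncated exponential
   `p(s) = ζ sinh(ζ(s_max − s)) / (cosh(ζ s_max) − 1) ≈ ζ e^{−ζs}`,
   with the curvature ζ equal to the inverse mean field size.
2. **Topology of pairwise correlations.** The order structure of the
   pairwise spike-train correlation matrix matches that of distances
   between points sampled uniformly from a hyperbolic ball (the native
   model: radial density ∝ sinh^(d−1) r, directions uniform on the
   sphere), rather than from a Euclidean cube. Betti curves of the
   clique-complex order filtration discriminate the two.
3. **Information optimality.** Among field-size distributions with
   matched mean (uniform) or mean and variance (log-normal),
   exponential sizes maximize the Fisher information a population
   carries about position, and the information-optimal ball radius
   grows with the logarithm of the number of neurons.

The package implements the full chain on synthetic data; recorded
datasets are outside its test scope.

## Synthetic sessions (`hypergeo.synth`)

* **Trajectory**: Ornstein–Uhlenbeck velocity (correlation time 1 s)
  with reflecting walls; the per-axis stationary velocity s.d. is set
  so the mean speed equals `speed_mean` (Rayleigh mean in 2-D,
  half-normal in 1-D). No locomotion model is implied by the analyses;
  any stationary space-filling walk would do, and the parameters are
  exposed.
* **Population**: per-cell field counts are gamma distributed (moment
  matching of mean/sd, rounded to the closest integer); per-field,
  per-axis Gaussian widths are i.i.d. exponential with mean 1/ζ,
  centers uniform in the arena, orientations uniform, amplitudes
  uniform on `amplitude_range`.
* **Defaults** (a 20-min, 180-cm square-box session): ζ = 0.05 /cm
  (mean width 20 cm), field counts gamma(mean 1.5, sd 1.2),
  amplitudes unif[4, 15] Hz, baseline 0.15 Hz. These were chosen once
  so that >90% of simulated cells fall in the 0.1–7 Hz band used to
  select putative active pyramidal cells: the baseline keeps
  field-less cells detectable above the 0.1 Hz floor, and the
  amplitude range keeps cells with several large fields below 7 Hz.
  The Fisher simulations use their own printed population statistics
  (amplitudes unif[5, 25], field counts gamma(0.98, 1.10) in the
  multi-field variant) and are unaffected by these session defaults.
* **Spiking**: per-bin Poisson thinning at the trajectory dt (default
  25 ms); spike times uniform within their bin. Exact-time algorithms
  are unnecessary at this resolution; a warning is logged if
  rate·dt exceeds 1 anywhere.
* **Shuffle control**: an independent uniform circular time shift per
  neuron (periodic boundary), preserving each neuron's rate and ISI
  statistics while destroying pairwise correlations.

What the generator does **not** emulate: theta rhythm and phase
precession, bursting, interneurons, behavioural states, non-Poisson
variability, and any anatomical organization. Passing tests therefore
demonstrate correctness of the analysis chain and its behaviour under
the stated statistical structure — not robustness to every property of
real recordings.

## Correlation (`hypergeo.correlation`)

`C_ij = max(N_ij, N_ji) / (τ_max · r_i · r_j · T)` with `N_ij` the
number of ordered spike pairs with `t_j − t_i ∈ [0, τ_max]` (inclusive
bounds — a measure-zero choice for continuous spike times). This
unbinned count equals the integrated cross-correlogram of the point
processes exactly; a binned variant is retained as a cross-check.
Defaults: τ_max = 1 s, rate band 0.1–7 Hz, optional restriction to the
last fraction of the session (2/3 for long sessions). The diagonal is
set to the matrix maximum so self-pairs rank first at every threshold;
it is plumbing, not a similarity. For independent trains
E[N_ij] = r_i r_j T τ_max, so chance level is C ≈ 1 with a small
positive bias from the max of the two directions.

## Topology (`hypergeo.topology`)

Betti curves β₁..β₃ of the flag complex of the graph containing the k
most-similar pairs, for every k (edge density ρ = k/C(n,2)). Computed
as persistent homology of the decreasing-similarity order filtration
over GF(2), implemented from scratch (no persistent-homology library
is a dependency): coboundary-matrix reduction with clearing, processed
per dimension, with dimension 0 handled by union–find. Columns in the
reduction are the *positive* m-simplices only, which keeps the
top-dimension cost proportional to the number of m-simplices rather
than (m+1)-simplices; a numba kernel does the column arithmetic. The
engine is validated against an independent brute-force oracle
(explicit boundary matrices, Gaussian elimination over GF(2)) on all
densities for n ≤ 8.

Numerical conventions: ties in similarity are broken by lexicographic
(i, j) order (deterministic; measure-zero for continuous data);
simplices with equal filtration value are ordered faces-first; the
density grid is exact (one step per edge); `integrated_betti` is the
step-function integral (mean of the values at k = 1..E), and the L1
distance is the analogous integral of |β − β_ref|, with step
re-gridding when grids differ. Display smoothing (boxcar of 1/50 of
the densities) is never used in statistics. β_m for m ≥ 1 requires
simplices up to dimension m+1 only, which bounds the enumeration.

## Geometry sampling and fitting (`hypergeo.geometry`, `hypergeo.geomfit`)

Hyperbolic samples fix ζ = 1 and vary the ball radius R_max
(equivalent to fixing the radius and varying curvature). Radii are
drawn by inverse-CDF of sinh^(d−1) on a dense grid; directions by
normalized Gaussians ("uniform angles" is read as uniform on the
sphere — the two differ for d > 2). Distances use the hyperbolic law
of cosines with the acosh argument clamped at 1 against round-off.
Euclidean samples are uniform in the unit cube. Model distance
matrices receive i.i.d. multiplicative Gaussian noise per unordered
pair, `D·(1 + ε N(0,1))` with ε = 0.05 by default (symmetry is
preserved by construction; the matrix is then negated into a
similarity).

Fitting compares experimental Betti curves to model ensembles
(default 300 repetitions; tests and examples use 20–50, the
accuracy/runtime dial): two-tailed percentile p-values for the
integrated Betti values and one-tailed percentiles for the L1
distance to the ensemble mean. The radius estimate maximizes the
product of the four β₁/β₂ p-values over a grid (default 5:0.5:24);
β₃ is excluded from the product because its integral is unstable at
small n, but is available for reporting. Grid ties break to the
smaller radius (parsimony). Because ensembles depend only on the
hypothesis and the point count — not on the data — `EnsembleLibrary`
caches them for reuse across matrices, which is what makes bootstrap
and multi-trial analyses affordable.

Two behaviours discovered in validation and worth knowing:

* A Euclidean-cube sample at n = 50 is *compatible* with small-radius
  hyperbolic balls (a small ball is nearly flat). The discriminating
  comparison is the converse one: matrices from a hyperbolic ball fit
  the hyperbolic family but are decisively rejected by the Euclidean
  ensemble.
* The radius search compares against ensembles that include ε = 0.05
  noise. In the undersampling simulation (41 points, ε = 0.5 per 1-s
  observation, observations averaged up to the readout time), short
  observations underestimate the radius severely, and the estimate
  returns to the truth once the averaged noise reaches the ensemble
  noise level (t ≈ (0.5/0.05)² = 100 s).

`dimension_chi2` scores hyperbolic dimensions by
χ² = mean over bins of D_expm/D_model on 10-bin-averaged curves
(experimental-vs-model-mean squared difference over the average
within-model squared deviation); zero-variance bins are floored at the
smallest positive D_model. `bootstrap_rmax` repeats the radius search
on random 75% neuron subsamples (pairwise correlations are unchanged
by dropping neurons, so the full matrix is subindexed) and reports the
median and central 95% interval.

## Place fields and covariates (`hypergeo.fields`)

Rate maps: occupancy and spike counts accumulated only while speed
exceeds 5 cm/s (central-difference speeds), binned at 1 cm (1-D) or
2 cm (2-D), both smoothed with the same Gaussian kernel (sd 10 cm)
*before* division — the occupancy-weighted order, which avoids edge
bias; zero-occupancy bins are undefined (NaN). The 2-Hz field
threshold applies to the smoothed rates, since the map is defined
post-smoothing. 1-D fields are maximal above-threshold runs with an
optional ≥15-cm length rule (off when small fields are the object of
study) and a ≥50%-overlap merge across running directions. 2-D fields
are 4-connected components; an optional watershed split at saddles
deeper than a prominence parameter replaces manual breakdown of
multi-peak fields and defaults off. Field "size" is length (1-D) or
area (2-D) with an equivalent-diameter accessor. Spatial information
uses the standard occupancy-weighted log₂ form (0·log 0 := 0; silent
maps give 0 by convention). Segment entropy discretizes turn angles
into 15 bins over [−π, π]; temporal familiarity is seconds per meter,
the reciprocal of the average first-pass speed, normalized by segment
length.

## Decoding (`hypergeo.decode`)

Maximum-likelihood decoding per 500-ms window under independent
Poisson likelihoods on 5×5-cm rate maps (flat prior; the n! term
cancels in the argmax). Rates are floored at 0.01 Hz before the log;
argmax ties break to the lowest pixel index; the true position is the
within-window average; windows slower than 5 cm/s are excluded. The
efficiency exponent fits `median_error = A exp(−c·n_spikes)` across
neuron-subsample sizes (nonlinear least squares; optional additive
offset off by default). c measures the error reduction bought by one
extra spike.

## Fisher information (`hypergeo.fisher`)

For independent Poisson neurons with Gaussian tuning, the closed form
`I(s) = Σ_i ∇f_i ∇f_iᵀ / f_i` (rates floored at 1e−6 in the division)
is averaged as det(I)^0.5 over iterations that redraw the population
and the stimulus each time. Size distributions: exponential(mean
1/ζ); uniform[0, 2/ζ] (matched mean); log-normal with σ_ln² = ln 2,
μ_ln = ln(1/ζ) − σ_ln²/2 (matched mean and variance — forced by the
moment equations). The multi-field variant draws per-cell field
counts from the rounded gamma law (printed statistics: mean 0.98,
sd 1.10) in a 1.8 × 1.8 m arena. In the radius sweep the radius plays
the exponent role of the size law (sizes ~ exp(−R σ) in arena units);
the absolute axis calibration of that mapping is not reproducible
from the printed material, so only the monotone logarithmic trend of
R_opt(N) and the extrapolation consistency are treated as
reproducible. The information-vs-radius curve is an asymmetric decay
with a shallow peak, so the second-order-polynomial peak finder is
applied locally (±3 grid steps around the empirical maximum);
boundary peaks are flagged.

## Curvature and information acquisition (`hypergeo.curvature`)

The Bayesian curvature estimator uses the window-truncated exponential
likelihood `P(s|ζ) = ζe^{−ζs}/Z(ζ)`, `Z = e^{−ζ s_l} − e^{−ζ s_u}`,
uniform prior on a grid of 400 log-spaced points in [1e−3, 1] /cm;
the estimate is the posterior maximum and the interval the central
95% of the grid CDF. The left-truncated ML variant (excluding fields
under 25 cm) is the closed form 1/mean(s − cutoff | s ≥ cutoff) by
memorylessness. The information curve
`I(T) = log(1 + T/t0) + (T/t0) log(1 + t0/T)` uses natural logs (its
least-squares fit has a free scale, so the base is unidentifiable;
entropies elsewhere are base-2 as is conventional). Note
`I(T) → log(T/t0) + 1`, so exact `R = log(T/t0*)` data is reproduced
by scale 1 with fitted `t0 = e·t0*`. Radius-growth fits offer both
the log-linear form and the scaled information curve (optional
intercept, off by default — overlay fits suggest scale-only).

The log-normal emergence simulation rejection-samples sinh laws
through a logistic acceptance `1/(1 + e^{−k(s − s₀)})` and tests the
accepted sizes against an ML-fitted log-normal with a histogram χ²
(equal-width bins, small-expected-count merging, df = bins − 1 − 2).
The sigmoid parameters and the eight curvatures are not printed in
the source material; the defaults (s₀ = 10 cm, k = 0.4 /cm, ζ from
0.02 to 0.06 /cm) were chosen once to sit in the qualitative regime
the simulation illustrates — gentle censoring of only the smallest
fields, the same bias visible in empirical size histograms whose
first column is missing. Sharper or larger-midpoint censoring leaves
a shoulder no log-normal matches, and the regime is config-exposed.

## Orchestration and I/O (`hypergeo.pipeline`)

CSV formats: spikes `neuron_id,time_s`; trajectories `t_s,x_cm[,y_cm]`;
an HDF5 container mirrors the field names. Loading validates units and
ordering (unsorted spikes are sorted with a warning, negative times
and mixed 1-D/2-D rows are errors). `run_pipeline` derives per-stage
seeds from one global seed via `SeedSequence.spawn`, so stages are
independently reproducible and a rerun is bit-identical. The package
is a library: the examples under `examples/` and the pipeline
functions are its operational surface (no shell entry points are
installed).

## Problem sizes and determinism

Tests and the acceptance script run everything at reduced but
statistically meaningful scale, chosen as the package's own
accuracy/runtime trade-off: ensembles of 20–50 repetitions (300 is
the analysis default), radius grids with 1.0 spacing over 5–16,
sessions of 8–20 minutes with 30–60 cells, 1000 Fisher iterations per
condition (10⁴ is the analysis default), 500 calibration replicates
for the curvature estimator, and 50 seeds for the emergence
simulation. All randomness flows from explicit seeds through
`numpy.random.default_rng`/`SeedSequence`; identical seeds give
bit-identical results on a fixed platform.

## Known limitations

* The persistence backend enumerates all C(n, m+2) candidate
  simplices; it is exact and fast for the population sizes this
  analysis targets (n ≲ 120 at β₁/β₂, n ≲ 60 at β₃) but is not a
  replacement for a general-purpose persistent-homology library.
* Radius estimates from a single matrix are noisy at 50-repetition
  ensembles (±2–3 at n = 50 points); medians over trials or the
  neuron bootstrap are the reliable summaries.
* Field sizes measured from detected 2-D fields (equivalent
  diameters of 2-Hz super-threshold regions of smoothed maps) are
  biased relative to the generative per-axis Gaussian widths, so
  curvature recovered from detected fields matches in order of
  magnitude, not exactly — the estimator itself is calibrated (93–97%
  coverage) on sizes drawn from its own model.
* The p-value products are valid as relative compatibility scores;
  they are not calibrated family-wise probabilities.
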