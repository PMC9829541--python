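"""Statistical comparison of Betti curves against geometry ensembles.

A candidate geometry is judged by sampling point clouds of the same
size as the neural population, computing noisy distance matrices,
negating them into similarities, and collecting the Betti curves over
many repetitions.  Two families of p-values compare an experimental
curve set to the ensemble: two-tailed percentiles of the integrated
Betti values, and one-tailed percentiles of the L1 distance to the
ensemble-mean curve.  The hyperbolic ball radius R_max is estimated by
maximizing, over a grid, the product of the four beta_1/beta_2
p-values (beta_3 is excluded from the product: its integral is
unstable at small neuron counts, though it can still be reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationMatrix
from .geometry import GeometrySpec, sample_distance_matrix
from .synth import SpikeTrainSet
from .topology import BettiCurveSet, betti_curves, integrated_betti, l1_curve_distance

__all__ = [
    "EnsembleResult",
    "GeometryFit",
    "EnsembleLibrary",
    "build_ensemble",
    "pvalue_integrated",
    "pvalue_l1",
    "optimal_rmax",
    "bootstrap_rmax",
    "chi2_statistic",
    "dimension_chi2",
    "undersampling_bias_sim",
    "DEFAULT_RMAX_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_RMAX_GRID = np.arange(5.0, 24.0 + 1e-9, 0.5)


@dataclass
class EnsembleResult:
    """Betti-curve ensemble of one geometry hypothesis."""

    spec: GeometrySpec
    n_points: int
    n_reps: int
    densities: np.ndarray
    rep_curves: np.ndarray       # (n_reps, max_dim, n_grid)
    mean_curves: np.ndarray      # (max_dim, n_grid)
    rep_integrated: np.ndarray   # (n_reps, max_dim)
    rep_l1: np.ndarray           # (n_reps, max_dim) distance to the mean curve

    @property
    def max_dim(self) -> int:
        return self.mean_curves.shape[0]


@dataclass
class GeometryFit:
    """Result of the R_max grid search for one experimental matrix."""

    grid: np.ndarray
    p_products: np.ndarray
    r_max: float
    p_int: dict           # m -> p-value at the optimum
    p_l1: dict
    per_grid: dict = field(default_factory=dict)  # R -> (p_int, p_l1)
    inconclusive: bool = False


def build_ensemble(spec: GeometrySpec, n_points: int, n_reps: int = 300,
                   seed=None, max_dim: int = 2) -> EnsembleResult:
    """Sample -> distances -> noise -> negate -> Betti, ``n_reps`` times."""
    if n_points < 4:
        raise ValueError("need at least 4 points")
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions")
    rng = np.random.default_rng(seed)
    curves = None
    for rep in range(n_reps):
        D = sample_distance_matrix(spec, n_points, rng)
        bc = betti_curves(-D.values, max_dim=max_dim)
        if curves is None:
            curves = np.empty((n_reps, max_dim, bc.curves.shape[1]),
                              dtype=np.int64)
            densities = bc.edge_densities
        curves[rep] = bc.curves
    mean_curves = curves.mean(axis=0)
    rep_integrated = curves[:, :, 1:].mean(axis=2)
    rep_l1 = np.abs(curves[:, :, 1:] - mean_curves[None, :, 1:]).mean(axis=2)
    return EnsembleResult(spec, n_points, n_reps, densities, curves,
                          mean_curves, rep_integrated, rep_l1)


def pvalue_integrated(experimental_value: float, ensemble: EnsembleResult,
                      m: int = 1) -> float:
    """Two-tailed percentile of an integrated Betti value in the ensemble."""
    model = ensemble.rep_integrated[:, m - 1]
    n = model.size
    lo = int(np.sum(model <= experimental_value))
    hi = int(np.sum(model >= experimental_value))
    return min(1.0, 2.0 * min(lo, hi) / n)


def pvalue_l1(experimental_curve: np.ndarray, ensemble: EnsembleResult,
              m: int = 1,
              experimental_densities: np.ndarray | None = None) -> float:
    """One-tailed percentile: fraction of reps with L1-to-mean >= data's."""
    mean = ensemble.mean_curves[m - 1]
    l1_exp = l1_curve_distance(np.asarray(experimental_curve, float), mean,
                               densities=experimental_densities,
                               reference_densities=ensemble.densities)
    return float(np.sum(ensemble.rep_l1[:, m - 1] >= l1_exp) / ensemble.n_reps)


class EnsembleLibrary:
    """Cache of geometry ensembles, reusable across experimental matrices.

    Ensembles depend only on the hypothesis (kind, dim, R_max, eps),
    the number of points, the repetition count and the seed — not on
    the data they are compared to — so fits of many matrices of equal
    size can share one library.
    """

    def __init__(self, n_points: int, n_reps: int = 300, dim: int = 3,
                 eps: float = 0.05, seed=0, max_dim: int = 2):
        self.n_points = n_points
        self.n_reps = n_reps
        self.dim = dim
        self.eps = eps
        self.seed = seed
        self.max_dim = max_dim
        self._cache: dict = {}

    def get(self, r_max: float | None = None,
            kind: str = "hyperbolic") -> EnsembleResult:
        key = (kind, None if r_max is None else round(float(r_max), 6))
        ens = self._cache.get(key)
        if ens is None:
            spec = GeometrySpec(kind, self.dim,
                                r_max=0.0 if r_max is None else float(r_max),
                                noise_eps=self.eps)
            # derive a stable per-hypothesis seed from the library seed
            child = np.random.SeedSequence(
                [self.seed, self.dim, self.n_points,
                 0 if r_max is None else int(round(float(r_max) * 1000))])
            ens = build_ensemble(spec, self.n_points, self.n_reps,
                                 seed=child, max_dim=self.max_dim)
            self._cache[key] = ens
        return ens


def _as_similarity(C_exp) -> np.ndarray:
    if isinstance(C_exp, CorrelationMatrix):
        return C_exp.values
    if isinstance(C_exp, BettiCurveSet):
        raise TypeError("pass the similarity matrix, not its Betti curves")
    return np.asarray(C_exp, dtype=float)


def optimal_rmax(C_exp, dim: int = 3, grid=None, n_reps: int = 300,
                 eps: float = 0.05, seed=0, max_dim: int = 2,
                 library: EnsembleLibrary | None = None) -> GeometryFit:
    """Grid search for the hyperbolic radius best explaining a matrix.

    For every R_max on the grid an ensemble of model Betti curves is
    built (or fetched from ``library``) and the four beta_1/beta_2
    p-values (integrated + L1, per curve) are computed; the optimum
    maximizes their product, ties broken toward the smaller radius
    (parsimony).
    """
    S = _as_similarity(C_exp)
    n_points = S.shape[0]
    if n_points < 4:
        raise ValueError("need at least 4 neurons")
    grid = DEFAULT_RMAX_GRID if grid is None else np.asarray(grid, float)
    if library is None:
        library = EnsembleLibrary(n_points, n_reps=n_reps, dim=dim, eps=eps,
                                  seed=seed, max_dim=max_dim)
    exp_bc = betti_curves(S, max_dim=max(2, library.max_dim))
    if not exp_bc.curves[:2].any():
        logger.warning("experimental beta_1 and beta_2 are identically zero; "
                       "fit is inconclusive")
        inconclusive = True
    else:
        inconclusive = False
    p_products = np.empty(grid.size)
    per_grid = {}
    for g, r in enumerate(grid):
        ens = library.get(r)
        p_int = {m: pvalue_integrated(
            integrated_betti(exp_bc.curve(m)), ens, m) for m in (1, 2)}
        p_l1 = {m: pvalue_l1(exp_bc.curve(m), ens, m,
                             experimental_densities=exp_bc.edge_densities)
                for m in (1, 2)}
        p_products[g] = p_int[1] * p_int[2] * p_l1[1] * p_l1[2]
        per_grid[float(r)] = (p_int, p_l1)
    best = int(np.argmax(p_products))  # argmax returns the first (smallest R) tie
    r_best = float(grid[best])
    p_int, p_l1 = per_grid[r_best]
    return GeometryFit(grid=grid, p_products=p_products, r_max=r_best,
                       p_int=p_int, p_l1=p_l1, per_grid=per_grid,
                       inconclusive=inconclusive)


def bootstrap_rmax(spikes: SpikeTrainSet, fraction: float = 0.75,
                   n_boot: int = 100, dim: int = 3, grid=None,
                   n_reps: int = 300, eps: float = 0.05, seed=0,
                   tau_max: float = 1.0, rate_band=(0.1, 7.0),
                   last_fraction: float | None = None,
                   max_dim: int = 2) -> dict:
    """Distribution of optimal R_max over random neuron subsamples.

    Each repetition keeps ``fraction`` of the eligible neurons (their
    pairwise correlations are unchanged by dropping others, so the full
    matrix is computed once and subindexed) and re-runs the radius
    search.  Returns median and central 95% interval.
    """
    from .correlation import correlation_matrix

    if spikes.n_neurons < 6:
        raise ValueError("need at least 6 neurons to bootstrap")
    C = correlation_matrix(spikes, tau_max=tau_max, rate_band=rate_band,
                           last_fraction=last_fraction)
    n = C.n_neurons
    m = max(4, int(round(fraction * n)))
    rng = np.random.default_rng(seed)
    library = EnsembleLibrary(m, n_reps=n_reps, dim=dim, eps=eps, seed=seed,
                              max_dim=max_dim)
    samples = np.empty(n_boot)
    for b in range(n_boot):
        keep = rng.choice(n, size=m, replace=False)
        sub = C.values[np.ix_(keep, keep)].copy()
        np.fill_diagonal(sub, sub.max())
        fit = optimal_rmax(sub, dim=dim, grid=grid, library=library)
        samples[b] = fit.r_max
    return {
        "samples": samples,
        "median": float(np.median(samples)),
        "ci95": (float(np.percentile(samples, 2.5)),
                 float(np.percentile(samples, 97.5))),
        "n_subsampled": m,
    }


def _bin_curve(curve: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a density-grid curve within ``n_bins`` equal bins."""
    curve = np.asarray(curve, dtype=float)[1:]  # drop the rho=0 sample
    edges = np.linspace(0, curve.size, n_bins + 1).astype(int)
    return np.array([curve[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])


def chi2_statistic(exp_curves: np.ndarray, ensemble: EnsembleResult,
                   n_bins: int = 10) -> float:
    """chi^2 misfit of experimental Betti curves against an ensemble.

    Mean over (curve, bin) of D_expm / D_model with D_expm the squared
    binned experimental-vs-model-mean difference and D_model the
    average squared binned rep-vs-mean deviation.  Zero-variance bins
    are floored at the smallest positive D_model.
    """
    exp_curves = np.atleast_2d(np.asarray(exp_curves, dtype=float))
    num = []
    den = []
    for m in range(1, min(exp_curves.shape[0], ensemble.max_dim) + 1):
        exp_b = _bin_curve(exp_curves[m - 1], n_bins)
        mean_b = _bin_curve(ensemble.mean_curves[m - 1], n_bins)
        rep_b = np.stack([_bin_curve(ensemble.rep_curves[i, m - 1], n_bins)
                          for i in range(ensemble.n_reps)])
        num.append((exp_b - mean_b) ** 2)
        den.append(((rep_b - mean_b[None]) ** 2).mean(axis=0))
    num = np.concatenate(num)
    den = np.concatenate(den)
    if np.any(den == 0):
        pos = den[den > 0]
        floor = pos.min() if pos.size else 1.0
        logger.warning("regularizing %d zero-variance bins",
                       int(np.sum(den == 0)))
        den = np.where(den == 0, floor, den)
    return float((num / den).mean())


def dimension_chi2(C_exp, dims=(2, 3, 4), r_max_per_dim: dict | None = None,
                   n_bins: int = 10, n_model_reps: int = 500, grid=None,
                   eps: float = 0.05, seed=0, max_dim: int = 2,
                   search_reps: int = 100) -> dict:
    """Goodness of fit (chi^2) of hyperbolic geometries of several dims.

    chi^2 = mean over bins of D_expm / D_model, where D_expm is the
    squared difference between the binned experimental curves and the
    binned model mean, and D_model the average squared deviation of the
    model reps from their mean.  Lower is better.  If ``r_max_per_dim``
    is not supplied, each dimension first gets its own radius search
    (``search_reps`` repetitions).
    """
    S = _as_similarity(C_exp)
    n_points = S.shape[0]
    exp_bc = betti_curves(S, max_dim=max_dim)
    results = {}
    for d in dims:
        if r_max_per_dim is not None and d in r_max_per_dim:
            r = float(r_max_per_dim[d])
        else:
            lib = EnsembleLibrary(n_points, n_reps=search_reps, dim=d,
                                  eps=eps, seed=seed, max_dim=max_dim)
            r = optimal_rmax(S, dim=d, grid=grid, library=lib).r_max
        spec = GeometrySpec("hyperbolic", d, r_max=r, noise_eps=eps)
        ens = build_ensemble(spec, n_points, n_model_reps,
                             seed=np.random.SeedSequence([seed, d, 7]),
                             max_dim=max_dim)
        results[d] = {"chi2": chi2_statistic(exp_bc.curves, ens, n_bins),
                      "r_max": r}
    return results


def undersampling_bias_sim(true_r: float = 10.0, n_points: int = 41,
                           eps: float = 0.5, readout_times=(1, 4, 16, 64, 100),
                           dim: int = 3, grid=None, n_reps: int = 300,
                           seed=0, library: EnsembleLibrary | None = None
                           ) -> dict:
    """Bias of the topological radius estimate under short observations.

    One point cloud is drawn from a hyperbolic ball of radius
    ``true_r``; each 1-s observation is the true distance matrix with
    fresh multiplicative noise (eps = 0.5).  At each readout time all
    observations so far are averaged (so the effective noise shrinks
    as 1/sqrt(t)) and the radius is re-estimated with the standard
    search.  Short observations underestimate the radius badly; the
    bias shrinks with averaging time and essentially vanishes once the
    residual noise reaches the ensemble noise level (t ~ (eps/0.05)^2
    seconds for the default model noise of 0.05).
    """
    readout_times = np.asarray(sorted(readout_times), dtype=int)
    if np.any(readout_times < 1):
        raise ValueError("readout times must be >= 1 s")
    rng = np.random.default_rng(seed)
    spec = GeometrySpec("hyperbolic", dim, r_max=true_r, noise_eps=0.0)
    D_true = sample_distance_matrix(spec, n_points, rng).values
    n = n_points
    iu = np.triu_indices(n, 1)
    if library is None:
        library = EnsembleLibrary(n_points, n_reps=n_reps, dim=dim,
                                  eps=0.05, seed=seed, max_dim=2)
    estimates = []
    running_sum = np.zeros(iu[0].size)
    t_done = 0
    for t_read in readout_times:
        k = int(t_read) - t_done
        noise = 1.0 + eps * rng.standard_normal((k, iu[0].size))
        running_sum += (D_true[iu][None, :] * noise).sum(axis=0)
        t_done = int(t_read)
        D_avg = np.zeros((n, n))
        D_avg[iu] = running_sum / t_done
        D_avg.T[iu] = D_avg[iu]
        fit = optimal_rmax(-D_avg, dim=dim, grid=grid, library=library)
        estimates.append(fit.r_max)
    return {"readout_times": readout_times,
            "estimates": np.asarray(estimates, dtype=float),
            "true_r": true_r}
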