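"""Bayesian maximum-likelihood position decoding and spike efficiency.

Position is decoded per time window (default 500 ms) from the spike
count vector {n_j} under independent Poisson likelihoods with per-pixel
mean rates lambda_ij from 5 x 5 cm rate maps:

    log p({n_j} | i) = sum_j [ n_j log(lambda_ij dt) - lambda_ij dt ]
                       (n_j! terms drop out of the argmax)

The decoded pixel is the argmax over i (flat prior); windows in which
the animal moved slower than 5 cm/s are excluded.  The efficiency
exponent c quantifies how much one extra spike reduces the median
decoding error: across neuron subsamples of different sizes the median
error falls off as A exp(-c n_spikes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .fields import RateMap, compute_rate_map
from .synth import SpikeTrainSet, Trajectory

__all__ = ["DecodingRun", "EfficiencyFit", "bayes_decode",
           "efficiency_exponent"]

logger = logging.getLogger(__name__)

RATE_FLOOR_HZ = 0.01  # avoids -inf log-rates in never-visited pixels


@dataclass
class DecodingRun:
    """Per-window decoding results."""

    window_s: float
    window_times: np.ndarray      # window centers, s
    decoded: np.ndarray           # (n_windows, ndim) cm
    true_positions: np.ndarray    # (n_windows, ndim) cm, window average
    errors: np.ndarray            # Euclidean cm
    spikes_per_window: np.ndarray

    @property
    def median_error(self) -> float:
        return float(np.median(self.errors))


@dataclass
class EfficiencyFit:
    """median_error = A exp(-c n_spikes) across subsample sizes."""

    c: float
    c_stderr: float
    amplitude: float
    n_spikes_levels: np.ndarray
    median_errors: np.ndarray


def _stack_maps(rate_maps: list[RateMap]):
    """Flatten 2-D rate maps into (n_pixels, n_neurons) with pixel centers."""
    shape = rate_maps[0].rates.shape
    ex, ey = rate_maps[0].bin_edges
    cx = (ex[:-1] + ex[1:]) / 2
    cy = (ey[:-1] + ey[1:]) / 2
    centers = np.column_stack([np.repeat(cx, cy.size),
                               np.tile(cy, cx.size)])
    lam = np.column_stack([np.nan_to_num(m.rates).ravel() for m in rate_maps])
    return np.maximum(lam, RATE_FLOOR_HZ), centers, shape


def bayes_decode(spikes: SpikeTrainSet, rate_maps: list[RateMap],
                 trajectory: Trajectory, window_s: float = 0.5,
                 speed_min: float = 5.0) -> DecodingRun:
    """Decode position per window from Poisson likelihoods (flat prior).

    ``rate_maps`` must be one 2-D map per neuron in ``spikes`` (same
    order).  Argmax ties break to the lowest pixel index.
    """
    if len(rate_maps) != spikes.n_neurons:
        raise ValueError("need one rate map per neuron")
    lam, centers, _ = _stack_maps(rate_maps)
    T = spikes.duration
    n_windows = int(T // window_s)
    if n_windows < 1:
        raise ValueError("session shorter than one decoding window")
    edges = np.arange(n_windows + 1) * window_s
    counts = np.column_stack([np.histogram(t, bins=edges)[0]
                              for t in spikes.spike_times])
    # window eligibility and true positions from the trajectory
    widx = np.clip(((trajectory.times) // window_s).astype(int), 0,
                   n_windows - 1)
    speeds = trajectory.speeds
    mean_speed = np.bincount(widx, weights=speeds, minlength=n_windows)
    n_samp = np.bincount(widx, minlength=n_windows)
    valid = n_samp > 0
    mean_speed[valid] /= n_samp[valid]
    true_pos = np.full((n_windows, trajectory.ndim), np.nan)
    for d in range(trajectory.ndim):
        s = np.bincount(widx, weights=trajectory.positions[:, d],
                        minlength=n_windows)
        true_pos[valid, d] = s[valid] / n_samp[valid]
    eligible = valid & (mean_speed >= speed_min)
    if not np.any(eligible):
        raise ValueError("no decodable windows above the speed threshold")
    log_lam = np.log(lam * window_s)          # (pixels, neurons)
    penalty = (lam * window_s).sum(axis=1)    # (pixels,)
    loglik = counts[eligible] @ log_lam.T - penalty[None, :]
    best = np.argmax(loglik, axis=1)          # first index on ties
    decoded = centers[best]
    errors = np.linalg.norm(decoded - true_pos[eligible], axis=1)
    wt = (edges[:-1] + edges[1:]) / 2
    return DecodingRun(window_s, wt[eligible], decoded, true_pos[eligible],
                       errors, counts[eligible].sum(axis=1))


def efficiency_exponent(spikes: SpikeTrainSet, trajectory: Trajectory,
                        subsample_range=(17, 25), bin_cm: float = 5.0,
                        smooth_sd: float = 10.0, window_s: float = 0.5,
                        rate_maps: list[RateMap] | None = None,
                        seed=None) -> EfficiencyFit:
    """Exponent c of median-error decay with spikes used for decoding.

    For each subsample size in ``subsample_range`` (inclusive) a random
    neuron subset is decoded; the (mean spikes per window, median
    error) pairs are fitted with A exp(-c n).  Needs at least 4 levels.
    """
    lo, hi = int(subsample_range[0]), int(subsample_range[1])
    sizes = np.arange(lo, hi + 1)
    if sizes.size < 4:
        raise ValueError("need at least 4 subsample levels")
    if spikes.n_neurons < hi:
        raise ValueError(f"need >= {hi} neurons, got {spikes.n_neurons}")
    rng = np.random.default_rng(seed)
    if rate_maps is None:
        rate_maps = [compute_rate_map(t, trajectory, bin_cm=bin_cm,
                                      smooth_sd=smooth_sd)
                     for t in spikes.spike_times]
    n_levels = sizes.size
    mean_spikes = np.empty(n_levels)
    med_err = np.empty(n_levels)
    for k, m in enumerate(sizes):
        pick = rng.choice(spikes.n_neurons, size=m, replace=False)
        run = bayes_decode(spikes.subset(pick), [rate_maps[i] for i in pick],
                           trajectory, window_s=window_s)
        mean_spikes[k] = run.spikes_per_window.mean()
        med_err[k] = run.median_error
    if np.any(np.diff(med_err[np.argsort(mean_spikes)]) > 0):
        logger.warning("median error is not monotone in spike count; "
                       "fit returned anyway")

    def model(n, A, c):
        return A * np.exp(-c * n)

    p0 = (med_err.max(), 1.0 / max(mean_spikes.mean(), 1e-9))
    popt, pcov = optimize.curve_fit(model, mean_spikes, med_err, p0=p0,
                                    maxfev=20000)
    return EfficiencyFit(c=float(popt[1]),
                         c_stderr=float(np.sqrt(pcov[1, 1])),
                         amplitude=float(popt[0]),
                         n_spikes_levels=mean_spikes,
                         median_errors=med_err)
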