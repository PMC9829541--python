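"""Pairwise spike-train correlation matrices.

The similarity between two neurons i and j on a timescale tau_max is

    C_ij = max(N_ij, N_ji) / (tau_max * r_i * r_j * T)

where N_ij counts ordered spike pairs with t_j - t_i in [0, tau_max],
r_i are mean rates over the analysis window, and T its length.  For
point processes this is the exact (unbinned) value of the integrated
cross-correlogram normalization used in clique-topology analyses of
neural data: for independent trains E[N_ij] = r_i r_j T tau_max, so
C ~ 1 at chance.  C is nonnegative and symmetric by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import SpikeTrainSet

__all__ = ["CorrelationMatrix", "pair_correlation", "pair_correlation_binned",
           "correlation_matrix"]


@dataclass
class CorrelationMatrix:
    """Symmetric nonnegative similarity matrix with its metadata."""

    values: np.ndarray
    tau_max: float
    neuron_ids: np.ndarray
    duration_used: float
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]


def _count_pairs(t_i: np.ndarray, t_j: np.ndarray, tau_max: float) -> int:
    """Ordered pairs with t_j - t_i in [0, tau_max], inclusive bounds."""
    lo = np.searchsorted(t_j, t_i, side="left")
    hi = np.searchsorted(t_j, t_i + tau_max, side="right")
    return int(np.sum(hi - lo))


def pair_correlation(spikes_i: np.ndarray, spikes_j: np.ndarray,
                     T: float, tau_max: float = 1.0) -> float:
    """Correlation of firing of one neuron pair (exact pair counting).

    Bounds at lag 0 and tau_max are inclusive — a measure-zero choice
    for continuous spike times, visible only in discretized toy data.
    """
    if T <= 0 or tau_max <= 0:
        raise ValueError("T and tau_max must be positive")
    t_i = np.asarray(spikes_i, dtype=float)
    t_j = np.asarray(spikes_j, dtype=float)
    if t_i.size == 0 or t_j.size == 0:
        raise ValueError("pair correlation undefined for empty trains")
    n_ij = _count_pairs(t_i, t_j, tau_max)
    n_ji = _count_pairs(t_j, t_i, tau_max)
    r_i = t_i.size / T
    r_j = t_j.size / T
    return max(n_ij, n_ji) / (tau_max * r_i * r_j * T)


def pair_correlation_binned(spikes_i, spikes_j, T: float,
                            tau_max: float = 1.0, bin_width: float = 0.01
                            ) -> float:
    """Discretized cross-correlogram variant, kept as a cross-check.

    Bins both trains at ``bin_width`` and integrates the binned ccg over
    [0, tau_max]; converges to :func:`pair_correlation` as the bin
    width shrinks.
    """
    t_i = np.asarray(spikes_i, dtype=float)
    t_j = np.asarray(spikes_j, dtype=float)
    if t_i.size == 0 or t_j.size == 0:
        raise ValueError("pair correlation undefined for empty trains")
    n_bins = int(np.ceil(T / bin_width))
    f_i = np.bincount(np.minimum((t_i / bin_width).astype(int), n_bins - 1),
                      minlength=n_bins)
    f_j = np.bincount(np.minimum((t_j / bin_width).astype(int), n_bins - 1),
                      minlength=n_bins)
    n_lags = int(round(tau_max / bin_width))
    n_ij = sum(int(f_i[: n_bins - k] @ f_j[k:]) for k in range(n_lags + 1))
    n_ji = sum(int(f_j[: n_bins - k] @ f_i[k:]) for k in range(n_lags + 1))
    r_i = t_i.size / T
    r_j = t_j.size / T
    return max(n_ij, n_ji) / (tau_max * r_i * r_j * T)


def correlation_matrix(spikes: SpikeTrainSet, tau_max: float = 1.0,
                       rate_band=(0.1, 7.0),
                       last_fraction: float | None = None
                       ) -> CorrelationMatrix:
    """Similarity matrix over the eligible neurons of a session.

    Neurons outside the mean-rate band (default 0.1-7 Hz, the putative
    active-pyramidal-cell band) are dropped.  ``last_fraction``
    restricts the analysis to the final fraction of the session (e.g.
    2/3 for long sessions whose early part is discarded); rates are
    recomputed on that window.  The diagonal is set to the matrix
    maximum so self-pairs rank first at every threshold — plumbing, not
    a similarity.
    """
    T = spikes.duration
    trains = spikes.spike_times
    ids = np.asarray(spikes.neuron_ids)
    if last_fraction is not None:
        if not 0 < last_fraction <= 1:
            raise ValueError("last_fraction must be in (0, 1]")
        t0 = T * (1 - last_fraction)
        trains = [t[t >= t0] - t0 for t in trains]
        T = T * last_fraction
    rates = np.array([t.size for t in trains]) / T
    eligible = (rates >= rate_band[0]) & (rates <= rate_band[1])
    if eligible.sum() < 3:
        raise ValueError(
            f"only {int(eligible.sum())} neurons in the rate band "
            f"{rate_band}; need at least 3")
    keep = np.flatnonzero(eligible)
    trains = [trains[i] for i in keep]
    n = len(trains)
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            C[a, b] = C[b, a] = pair_correlation(trains[a], trains[b], T,
                                                 tau_max)
    np.fill_diagonal(C, C.max() if n else 0.0)
    return CorrelationMatrix(C, tau_max, ids[keep], T,
                             meta={"rate_band": tuple(rate_band),
                                   "last_fraction": last_fraction})
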