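"""Synthetic place-cell sessions: trajectories, populations, spikes.

Generates data with the statistical structure the downstream analyses
assume for hippocampal CA1 recordings: an animal exploring a linear
track or square box, place cells with Gaussian tuning whose per-axis
field widths are exponentially distributed (mean 1/zeta, the inverse of
the representation curvature), per-cell field counts drawn from a
rounded gamma distribution, and inhomogeneous-Poisson spiking.

Everything is driven by one explicit seed (any value accepted by
``numpy.random.default_rng``); generators record it in their metadata.

What this does *not* emulate: theta rhythm and phase precession,
bursting, interneurons, or behavioural state changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "PlaceCellModel",
    "SpikeTrainSet",
    "simulate_trajectory",
    "generate_population",
    "simulate_spikes",
    "shuffle_spike_trains",
]

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Timestamped positions on a uniform time grid.

    times in seconds (constant step dt), positions in cm with one
    column per spatial dimension; speeds (cm/s) are central-difference
    estimates.
    """

    times: np.ndarray
    positions: np.ndarray  # (n, ndim) cm
    arena_cm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] != self.times.size:
            if self.positions.shape[1] == self.times.size:
                self.positions = self.positions.T
            else:
                raise ValueError("times and positions length mismatch")
        if self.times.size > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("times must increase with a constant step")

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            return 0.0
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) + self.dt

    @property
    def speeds(self) -> np.ndarray:
        """Central-difference speed, cm/s (zero for single-sample runs)."""
        if self.times.size < 2:
            return np.zeros(self.times.size)
        grad = np.gradient(self.positions, self.times, axis=0)
        return np.linalg.norm(grad, axis=1)


@dataclass
class PlaceCellModel:
    """Gaussian multi-field tuning curve of one cell.

    Per field: amplitude (Hz), center (cm), per-axis widths sigma (cm)
    and, in 2D, an orientation theta (rad) rotating the covariance
    R(theta) diag(sigma1^2, sigma2^2) R(theta)^T.
    """

    amplitudes: np.ndarray  # (k,) Hz
    centers: np.ndarray     # (k, ndim) cm
    sigmas: np.ndarray      # (k, ndim) cm
    thetas: np.ndarray      # (k,) rad, ignored for 1D
    baseline_rate: float = 0.0

    def __post_init__(self):
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, float))
        self.thetas = np.atleast_1d(np.asarray(self.thetas, float))
        if np.any(self.amplitudes <= 0):
            raise ValueError("field amplitudes must be positive")
        if np.any(self.sigmas <= 0):
            raise ValueError("field widths must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline rate must be >= 0")

    @property
    def n_fields(self) -> int:
        return self.amplitudes.size

    def rate(self, positions: np.ndarray) -> np.ndarray:
        """Firing rate (Hz) at each position, (n, ndim) or (n,) input."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if pos.shape[1] != self.centers.shape[1] and pos.shape[0] == self.centers.shape[1]:
            pos = pos.T
        out = np.full(pos.shape[0], self.baseline_rate, dtype=float)
        for k in range(self.n_fields):
            d = pos - self.centers[k]
            if pos.shape[1] == 2:
                c, s = np.cos(self.thetas[k]), np.sin(self.thetas[k])
                u1 = c * d[:, 0] + s * d[:, 1]
                u2 = -s * d[:, 0] + c * d[:, 1]
                q = (u1 / self.sigmas[k, 0]) ** 2 + (u2 / self.sigmas[k, 1]) ** 2
            else:
                q = (d[:, 0] / self.sigmas[k, 0]) ** 2
            out += self.amplitudes[k] * np.exp(-0.5 * q)
        return out


@dataclass
class SpikeTrainSet:
    """Per-neuron sorted spike times on [0, T]."""

    spike_times: list  # list of 1-D arrays, seconds
    duration: float
    neuron_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spike_times = [np.sort(np.asarray(t, dtype=float))
                            for t in self.spike_times]
        for t in self.spike_times:
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError("spike times outside [0, duration]")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(len(self.spike_times))
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    @property
    def mean_rates(self) -> np.ndarray:
        """Spike count / duration per neuron, Hz."""
        return np.array([t.size for t in self.spike_times]) / self.duration

    def subset(self, indices) -> "SpikeTrainSet":
        indices = np.asarray(indices)
        return SpikeTrainSet([self.spike_times[i] for i in indices],
                             self.duration, self.neuron_ids[indices],
                             dict(self.meta))


def simulate_trajectory(arena_cm: float, duration: float, dt: float = 0.025,
                        speed_mean: float = 10.0, ndim: int = 2,
                        speed_tau: float = 1.0,
                        seed=None) -> Trajectory:
    """Smoothed random walk in a box (or on a line) with reflecting walls.

    The velocity follows an Ornstein-Uhlenbeck process with correlation
    time ``speed_tau`` whose stationary speed distribution has mean
    ``speed_mean`` — any stationary space-filling walk serves the
    downstream analyses; this one is merely convenient and smooth.
    """
    if arena_cm <= 0:
        raise ValueError("arena dimension must be positive")
    if duration <= 0 or dt <= 0 or speed_mean <= 0:
        raise ValueError("duration, dt and speed_mean must be positive")
    rng = np.random.default_rng(seed)
    n = max(1, int(round(duration / dt)))
    times = np.arange(n) * dt
    # stationary per-axis velocity sd giving the requested mean speed
    if ndim == 2:
        sigma_v = speed_mean / np.sqrt(np.pi / 2)  # Rayleigh mean
    elif ndim == 1:
        sigma_v = speed_mean / np.sqrt(2 / np.pi)  # half-normal mean
    else:
        raise ValueError("only 1-D and 2-D arenas are supported")
    alpha = np.exp(-dt / speed_tau)
    noise_sd = sigma_v * np.sqrt(1 - alpha ** 2)
    v = rng.standard_normal(ndim) * sigma_v
    pos = rng.uniform(0, arena_cm, size=ndim)
    positions = np.empty((n, ndim))
    positions[0] = pos
    for t in range(1, n):
        v = alpha * v + noise_sd * rng.standard_normal(ndim)
        pos = pos + v * dt
        # reflecting boundaries
        for d in range(ndim):
            if pos[d] < 0:
                pos[d] = -pos[d]
                v[d] = -v[d]
            elif pos[d] > arena_cm:
                pos[d] = 2 * arena_cm - pos[d]
                v[d] = -v[d]
        positions[t] = np.clip(pos, 0, arena_cm)
    return Trajectory(times, positions, arena_cm,
                      meta={"seed": seed, "speed_mean": speed_mean,
                            "speed_tau": speed_tau})


def _gamma_counts(mean: float, sd: float, n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Field counts: gamma by moment matching, rounded to closest integer."""
    if mean <= 0 or sd < 0:
        raise ValueError("field_count_mean must be > 0 and sd >= 0")
    if sd == 0:
        return np.full(n, int(round(mean)))
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return np.round(rng.gamma(shape, scale, size=n)).astype(int)


def generate_population(n_neurons: int, zeta: float = 0.05,
                        field_count_mean: float = 1.5,
                        field_count_sd: float = 1.2,
                        arena_cm: float = 180.0, ndim: int = 2,
                        amplitude_range=(4.0, 15.0),
                        baseline_rate: float = 0.15,
                        seed=None) -> list[PlaceCellModel]:
    """Place-cell population with exponential field-size statistics.

    Per cell the number of fields is gamma distributed (shape and scale
    by moment matching of ``field_count_mean``/``field_count_sd``,
    rounded to the closest integer); per field the per-axis Gaussian
    widths are i.i.d. exponential with mean 1/zeta, amplitudes are
    uniform on ``amplitude_range`` (Hz), centers uniform in the arena
    and orientations uniform in [0, 2 pi).
    """
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    if zeta <= 0:
        raise ValueError("curvature zeta must be positive")
    rng = np.random.default_rng(seed)
    counts = _gamma_counts(field_count_mean, field_count_sd, n_neurons, rng)
    cells = []
    for k in counts:
        k = int(k)
        if k == 0:
            cells.append(PlaceCellModel(
                amplitudes=np.ones(0), centers=np.zeros((0, ndim)),
                sigmas=np.ones((0, ndim)), thetas=np.zeros(0),
                baseline_rate=baseline_rate))
            continue
        cells.append(PlaceCellModel(
            amplitudes=rng.uniform(*amplitude_range, size=k),
            centers=rng.uniform(0, arena_cm, size=(k, ndim)),
            sigmas=rng.exponential(1.0 / zeta, size=(k, ndim)),
            thetas=rng.uniform(0, 2 * np.pi, size=k),
            baseline_rate=baseline_rate))
    return cells


def simulate_spikes(population: list[PlaceCellModel], trajectory: Trajectory,
                    seed=None) -> SpikeTrainSet:
    """Inhomogeneous-Poisson spikes along a trajectory.

    Per time bin dt the spike count is Poisson(f_i(pos(t)) * dt); spike
    times are placed uniformly within their bin.  Valid as long as
    rate * dt stays small; a warning is logged if it exceeds 1
    anywhere (the count model remains correct, but bin-level timing
    becomes coarse).
    """
    rng = np.random.default_rng(seed)
    dt = trajectory.dt if trajectory.times.size > 1 else 0.0
    trains = []
    for cell in population:
        if trajectory.times.size < 2 or dt == 0.0:
            trains.append(np.zeros(0))
            continue
        rates = cell.rate(trajectory.positions)
        lam = rates * dt
        if np.any(lam > 1.0):
            logger.warning("rate*dt exceeds 1 in %d bins; spike timing is "
                           "coarse at this dt", int(np.sum(lam > 1.0)))
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(counts.size), counts)
        times = trajectory.times[idx] + rng.uniform(0, dt, size=idx.size)
        trains.append(np.sort(times))
    duration = trajectory.duration if trajectory.times.size > 1 else trajectory.dt
    if duration == 0.0:
        duration = np.finfo(float).tiny
    return SpikeTrainSet(trains, duration, meta={"seed": seed})


def shuffle_spike_trains(spikes: SpikeTrainSet, seed=None) -> SpikeTrainSet:
    """Independent circular time shift of each neuron's spike train.

    A uniform lag in [0, T) is added per neuron with periodic boundary,
    preserving each neuron's count, rate and (up to the one wrap point)
    its ISI statistics while destroying pairwise correlations.
    """
    if spikes.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    T = spikes.duration
    shifted = []
    for t in spikes.spike_times:
        lag = rng.uniform(0, T)
        shifted.append(np.sort((t + lag) % T))
    return SpikeTrainSet(shifted, T, spikes.neuron_ids.copy(),
                         {**spikes.meta, "shuffled": True, "shuffle_seed": seed})
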