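"""Rate maps, place-field detection, and behavioural covariates.

Rate maps are occupancy-normalized spike maps: spikes and occupancy
are accumulated in spatial bins (1 cm for linear tracks, 2 x 2 cm for
boxes) using only periods when the animal runs faster than a speed
threshold (default 5 cm/s), both are smoothed with the same Gaussian
kernel (default sd 10 cm), and the rate is their ratio.  Smoothing
numerator and denominator separately before dividing is the
occupancy-weighted choice that avoids edge bias.  Place fields are
contiguous regions above a rate threshold (default 2 Hz); for linear
tracks the classic criterion additionally requires >= 15 contiguous
centimeters, which can be switched off when small fields are the
object of study (curvature estimation).

Behavioural covariates: the entropy of discretized turn angles per
track segment, the temporal familiarity (seconds spent per meter, the
reciprocal of the average traversal speed), and per-field first-pass
speeds (field size / duration of the first traversal with a spike).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synth import Trajectory

__all__ = [
    "RateMap",
    "PlaceField",
    "SegmentStats",
    "compute_rate_map",
    "detect_place_fields_1d",
    "merge_directional_fields",
    "detect_place_fields_2d",
    "spatial_information",
    "segment_entropy",
    "familiarity_and_first_pass",
]

logger = logging.getLogger(__name__)


@dataclass
class RateMap:
    """Occupancy-normalized, speed-filtered, smoothed firing map."""

    bin_edges: list           # one edge array per spatial dimension
    occupancy: np.ndarray     # seconds per bin (smoothed)
    spike_counts: np.ndarray  # spikes per bin (smoothed)
    rates: np.ndarray         # Hz; NaN where occupancy is zero
    bin_cm: float
    smooth_sd: float
    speed_min: float
    raw_occupancy: np.ndarray | None = None
    raw_counts: np.ndarray | None = None

    @property
    def ndim(self) -> int:
        return len(self.bin_edges)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.rates)


@dataclass
class PlaceField:
    """Contiguous above-threshold region of a rate map."""

    bins: np.ndarray          # indices into the map (1D) or (k, 2) array
    size: float               # cm (1D length) or cm^2 (2D area)
    peak_rate: float
    center: np.ndarray        # cm, rate-weighted centroid
    direction: int = 0        # directional maps: 0/1; 0 when unused
    first_pass_speed: float | None = None

    def equivalent_diameter(self) -> float:
        """Diameter of the circle with the field's area (2D size in cm)."""
        return float(2.0 * np.sqrt(self.size / np.pi))


@dataclass
class SegmentStats:
    """Per-segment behavioural covariates on a linear track."""

    segment_index: int
    entropy_bits: float | None
    familiarity_s_per_m: float
    mean_speed_cm_s: float


def compute_rate_map(spike_times: np.ndarray, trajectory: Trajectory,
                     bin_cm: float = 2.0, smooth_sd: float = 10.0,
                     speed_min: float = 5.0) -> RateMap:
    """Rate map of one neuron along a trajectory.

    Occupancy (sample dt per bin) and spike counts are accumulated only
    while speed > ``speed_min``; both are Gaussian-smoothed with sd
    ``smooth_sd`` (cm) and divided.  Set ``smooth_sd=0`` to skip
    smoothing.
    """
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    speeds = trajectory.speeds
    moving = speeds > speed_min
    if not np.any(moving):
        raise ValueError("no eligible occupancy: all speeds below threshold")
    dt = trajectory.dt
    ndim = trajectory.ndim
    edges = [np.arange(0, trajectory.arena_cm + bin_cm, bin_cm)
             for _ in range(ndim)]
    pos = trajectory.positions[moving]
    occ, _ = np.histogramdd(pos, bins=edges)
    occ *= dt
    # spike positions by interpolation; spike eligibility from the
    # enclosing trajectory sample
    idx = np.clip(np.searchsorted(trajectory.times, spike_times) - 1,
                  0, trajectory.times.size - 1)
    keep = moving[idx]
    spike_pos = np.column_stack([
        np.interp(spike_times[keep], trajectory.times,
                  trajectory.positions[:, d]) for d in range(ndim)])
    counts, _ = np.histogramdd(spike_pos, bins=edges)
    raw_occ, raw_counts = occ.copy(), counts.copy()
    if smooth_sd > 0:
        sd_bins = smooth_sd / bin_cm
        occ = ndimage.gaussian_filter(occ, sd_bins)
        counts = ndimage.gaussian_filter(counts, sd_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, counts / np.where(occ > 0, occ, 1.0),
                         np.nan)
    return RateMap(edges, occ, counts, rates, bin_cm, smooth_sd, speed_min,
                   raw_occupancy=raw_occ, raw_counts=raw_counts)


def _field_from_bins(rate_map: RateMap, bins: np.ndarray,
                     direction: int = 0) -> PlaceField:
    rates = rate_map.rates
    if rate_map.ndim == 1:
        vals = rates[bins]
        centers = (rate_map.bin_edges[0][bins]
                   + rate_map.bin_edges[0][bins + 1]) / 2
        size = bins.size * rate_map.bin_cm
        center = np.atleast_1d((vals * centers).sum() / vals.sum())
    else:
        vals = rates[bins[:, 0], bins[:, 1]]
        cx = (rate_map.bin_edges[0][bins[:, 0]]
              + rate_map.bin_edges[0][bins[:, 0] + 1]) / 2
        cy = (rate_map.bin_edges[1][bins[:, 1]]
              + rate_map.bin_edges[1][bins[:, 1] + 1]) / 2
        size = bins.shape[0] * rate_map.bin_cm ** 2
        center = np.array([(vals * cx).sum(), (vals * cy).sum()]) / vals.sum()
    return PlaceField(bins=bins, size=float(size),
                      peak_rate=float(np.nanmax(vals)), center=center,
                      direction=direction)


def detect_place_fields_1d(rate_map: RateMap, rate_thresh: float = 2.0,
                           min_len: float = 15.0,
                           enforce_min_len: bool = True,
                           direction: int = 0) -> list[PlaceField]:
    """Maximal above-threshold runs of a 1-D rate map."""
    if rate_map.ndim != 1:
        raise ValueError("expected a 1-D rate map")
    above = np.nan_to_num(rate_map.rates) > rate_thresh
    fields = []
    labels, n_runs = ndimage.label(above)
    for lab in range(1, n_runs + 1):
        bins = np.flatnonzero(labels == lab)
        length = bins.size * rate_map.bin_cm
        if enforce_min_len and length < min_len:
            continue
        fields.append(_field_from_bins(rate_map, bins, direction=direction))
    return fields


def merge_directional_fields(fields_out: list[PlaceField],
                             fields_in: list[PlaceField]) -> list[PlaceField]:
    """Merge fields detected per running direction on a linear track.

    Two fields are merged when either covers at least 50% of the other;
    the merged field is the union of bins (rates taken from the field
    with the higher peak).
    """
    merged = []
    used_in = set()
    for f_out in fields_out:
        partner = None
        set_out = set(f_out.bins.tolist())
        for k, f_in in enumerate(fields_in):
            if k in used_in:
                continue
            set_in = set(f_in.bins.tolist())
            overlap = len(set_out & set_in)
            if overlap >= 0.5 * len(set_out) or overlap >= 0.5 * len(set_in):
                partner = k
                break
        if partner is None:
            merged.append(f_out)
        else:
            used_in.add(partner)
            f_in = fields_in[partner]
            bins = np.array(sorted(set_out | set(f_in.bins.tolist())))
            better = f_out if f_out.peak_rate >= f_in.peak_rate else f_in
            merged.append(PlaceField(
                bins=bins, size=float(bins.size *
                                      (f_out.size / max(f_out.bins.size, 1))),
                peak_rate=max(f_out.peak_rate, f_in.peak_rate),
                center=better.center, direction=0))
    merged.extend(f for k, f in enumerate(fields_in) if k not in used_in)
    return merged


def detect_place_fields_2d(rate_map: RateMap, rate_thresh: float = 2.0,
                           split_multipeak: bool = False,
                           peak_prominence: float = 1.0) -> list[PlaceField]:
    """4-connected above-threshold regions of a 2-D rate map.

    With ``split_multipeak`` regions containing several local maxima
    separated by a saddle deeper than ``peak_prominence`` (Hz) are
    split along the watershed between the peaks — an automated stand-in
    for manual breakdown of multi-peaked fields.
    """
    if rate_map.ndim != 2:
        raise ValueError("expected a 2-D rate map")
    rates = np.nan_to_num(rate_map.rates)
    above = rates > rate_thresh
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n_regions = ndimage.label(above, structure=structure)
    fields = []
    for lab in range(1, n_regions + 1):
        mask = labels == lab
        if split_multipeak:
            sub = _split_region(rates, mask, peak_prominence, structure)
        else:
            sub = [mask]
        for piece in sub:
            bins = np.argwhere(piece)
            fields.append(_field_from_bins(rate_map, bins))
    return fields


def _split_region(rates, mask, prominence, structure):
    """Watershed split of one region at saddles between prominent peaks."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    local = np.where(mask, rates, 0.0)
    peaks = peak_local_max(local, labels=mask.astype(int), min_distance=2,
                           threshold_abs=0.0)
    if peaks.shape[0] <= 1:
        return [mask]
    # keep peaks that rise at least `prominence` above the best saddle
    markers = np.zeros_like(mask, dtype=int)
    vals = local[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-vals)
    kept = [peaks[order[0]]]
    for k in order[1:]:
        # saddle level: highest level at which this peak connects to a kept one
        p = peaks[k]
        lvl = None
        for h in np.linspace(local[p[0], p[1]], 0, 20):
            lab, _ = ndimage.label(local >= h, structure=structure)
            if any(lab[p[0], p[1]] == lab[q[0], q[1]] for q in kept):
                lvl = h
                break
        if lvl is None or local[p[0], p[1]] - lvl >= prominence:
            kept.append(p)
    if len(kept) <= 1:
        return [mask]
    for i, p in enumerate(kept):
        markers[p[0], p[1]] = i + 1
    ws = watershed(-local, markers=markers, mask=mask)
    return [ws == i + 1 for i in range(len(kept))]


def spatial_information(rate_map: RateMap) -> tuple[float, float]:
    """Skaggs spatial information of a rate map.

    bits/spike = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda),
    bits/s     = sum_i p_i lambda_i log2(lambda_i / lambda),
    with p_i the occupancy distribution and lambda the overall mean
    rate; 0 * log 0 := 0.  A silent map yields (0, 0) by convention.
    """
    defined = rate_map.defined
    occ = rate_map.occupancy[defined]
    if occ.sum() <= 0:
        raise ValueError("rate map has no defined occupancy")
    p = occ / occ.sum()
    lam = rate_map.rates[defined]
    lam_bar = float((p * lam).sum())
    if lam_bar == 0:
        logger.info("silent map: spatial information set to 0 by convention")
        return 0.0, 0.0
    ratio = lam / lam_bar
    term = np.where(ratio > 0, ratio * np.log2(np.where(ratio > 0, ratio, 1)),
                    0.0)
    bits_per_spike = float((p * term).sum())
    bits_per_s = bits_per_spike * lam_bar
    return bits_per_spike, bits_per_s


def segment_entropy(turn_angles, n_bins: int = 15) -> float:
    """Entropy (bits) of discretized turn angles; 0 for straight segments."""
    angles = np.asarray(turn_angles, dtype=float)
    if angles.size == 0:
        raise ValueError("no turn angles supplied")
    if not np.all(np.isfinite(angles)):
        raise ValueError("turn angles must be finite")
    counts, _ = np.histogram(angles, bins=n_bins, range=(-np.pi, np.pi))
    p = counts[counts > 0] / angles.size
    return float(-(p * np.log2(p)).sum())


def _passes_through(trajectory: Trajectory, lo: float, hi: float):
    """Contiguous index intervals during which position is in [lo, hi]."""
    x = trajectory.positions[:, 0]
    inside = (x >= lo) & (x <= hi)
    labels, n = ndimage.label(inside)
    out = []
    for lab in range(1, n + 1):
        idx = np.flatnonzero(labels == lab)
        out.append((idx[0], idx[-1]))
    return out


def familiarity_and_first_pass(fields: list[PlaceField],
                               spike_trains: list[np.ndarray],
                               field_neurons: list[int],
                               trajectory: Trajectory,
                               segment_len_cm: float = 100.0):
    """Per-field first-pass speeds and per-segment familiarity (1-D).

    First-pass speed of a field = field size / duration of the first
    traversal through the field during which its neuron fired at least
    one spike; fields never traversed with a spike are excluded.  Per
    ``segment_len_cm`` segment of the track, the average segment speed
    is (sum of member field sizes) / (sum of their first-pass
    durations) and the temporal familiarity is its reciprocal in s per
    meter, normalized by segment length when it is not 1 m.

    Returns (segment_stats, fields_with_speeds).
    """
    if trajectory.ndim != 1:
        raise ValueError("familiarity analysis expects a 1-D trajectory")
    dt = trajectory.dt
    out_fields = []
    for f, neuron in zip(fields, field_neurons):
        lo = float(f.center[0] - f.size / 2)
        hi = float(f.center[0] + f.size / 2)
        spikes = np.asarray(spike_trains[neuron])
        duration = None
        for i0, i1 in _passes_through(trajectory, lo, hi):
            t0, t1 = trajectory.times[i0], trajectory.times[i1] + dt
            if np.any((spikes >= t0) & (spikes <= t1)):
                duration = t1 - t0
                break
        if duration is None or duration <= 0:
            logger.info("field at %.1f cm never traversed with a spike; "
                        "excluded", f.center[0])
            continue
        speed = f.size / duration
        out_fields.append(PlaceField(f.bins, f.size, f.peak_rate, f.center,
                                     f.direction, first_pass_speed=speed))
    n_segments = int(np.ceil(trajectory.arena_cm / segment_len_cm))
    stats = []
    for seg in range(n_segments):
        lo, hi = seg * segment_len_cm, (seg + 1) * segment_len_cm
        members = [f for f in out_fields if lo <= f.center[0] < hi]
        if not members:
            continue
        total_len = sum(f.size for f in members)
        total_dur = sum(f.size / f.first_pass_speed for f in members)
        speed = total_len / total_dur  # cm/s
        # familiarity in s per m, comparable across segment lengths
        familiarity = 100.0 / speed
        stats.append(SegmentStats(segment_index=seg, entropy_bits=None,
                                  familiarity_s_per_m=familiarity,
                                  mean_speed_cm_s=speed))
    return stats, out_fields
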