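import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypergeo.fields import (PlaceField, RateMap, compute_rate_map,
                             detect_place_fields_1d, detect_place_fields_2d,
                             familiarity_and_first_pass,
                             merge_directional_fields, segment_entropy,
                             spatial_information)
from hypergeo.synth import PlaceCellModel, Trajectory, simulate_spikes, \
    simulate_trajectory


def _map_from_rates(rates, bin_cm=1.0, occupancy=None):
    """Hand-built 1-D RateMap for rule tests."""
    rates = np.asarray(rates, dtype=float)
    occ = np.ones_like(rates) if occupancy is None else np.asarray(occupancy,
                                                                   float)
    edges = [np.arange(rates.size + 1) * bin_cm]
    return RateMap(edges, occ, rates * occ, rates, bin_cm, 0.0, 5.0)


def test_single_spike_in_one_bin_with_one_second_occupancy_is_one_hz():
    n = 400
    times = np.arange(n) * 0.025  # parked 10 s... but must exceed speed 5
    # constant-velocity sweep: 10 cm/s, so 1 s in each 10-cm bin
    pos = (times * 10.0)[:, None]
    traj = Trajectory(times, pos, 100.0)
    rm = compute_rate_map(np.array([5.0]), traj, bin_cm=10.0, smooth_sd=0.0)
    k = int(np.argmax(rm.spike_counts))
    assert rm.rates[k] == pytest.approx(1.0, rel=0.05)


def test_all_slow_periods_raise():
    n = 100
    traj = Trajectory(np.arange(n) * 0.025, np.full((n, 1), 3.0), 100.0)
    with pytest.raises(ValueError):
        compute_rate_map(np.array([1.0]), traj, bin_cm=1.0)


def test_constant_rate_cell_gives_a_flat_map(demo_session):
    """A pure-baseline cell yields a spatially flat smoothed map."""
    traj = simulate_trajectory(100.0, 600.0, seed=21)
    cell = PlaceCellModel(np.ones(0), np.zeros((0, 2)), np.ones((0, 2)),
                          np.zeros(0), baseline_rate=4.0)
    spikes = simulate_spikes([cell], traj, seed=22)
    rm = compute_rate_map(spikes.spike_times[0], traj, bin_cm=2.0,
                          smooth_sd=10.0)
    rates = rm.rates[rm.defined & (rm.occupancy > rm.occupancy.mean())]
    assert np.median(rates) == pytest.approx(4.0, rel=0.15)
    assert rates.std() < 1.5


def test_spike_mass_is_conserved_before_smoothing():
    traj = simulate_trajectory(100.0, 300.0, seed=23)
    cell = PlaceCellModel([8.0], [[50.0, 50.0]], [[15.0, 15.0]], [0.0],
                          baseline_rate=0.5)
    spikes = simulate_spikes([cell], traj, seed=24)
    rm = compute_rate_map(spikes.spike_times[0], traj, bin_cm=2.0)
    t = spikes.spike_times[0]
    idx = np.clip(np.searchsorted(traj.times, t) - 1, 0, traj.times.size - 1)
    eligible = traj.speeds[idx] > 5.0
    assert rm.raw_counts.sum() == pytest.approx(eligible.sum())


def test_1d_field_detection_rules():
    rm = _map_from_rates([0, 3, 3, 3, 0])
    fields = detect_place_fields_1d(rm, enforce_min_len=False)
    assert len(fields) == 1 and fields[0].size == pytest.approx(3.0)
    assert detect_place_fields_1d(rm, enforce_min_len=True) == []
    rm20 = _map_from_rates([0] * 2 + [5] * 20 + [0] * 2)
    long_fields = detect_place_fields_1d(rm20, enforce_min_len=True)
    assert len(long_fields) == 1 and long_fields[0].size == pytest.approx(20.0)


def test_directional_fields_merge_at_half_overlap():
    rm_out = _map_from_rates([0] * 5 + [4] * 10 + [0] * 5)
    rm_in = _map_from_rates([0] * 9 + [6] * 10 + [0] * 1)
    f_out = detect_place_fields_1d(rm_out, enforce_min_len=False,
                                   direction=0)
    f_in = detect_place_fields_1d(rm_in, enforce_min_len=False, direction=1)
    merged = merge_directional_fields(f_out, f_in)  # 60% overlap -> merge
    assert len(merged) == 1
    assert merged[0].bins.size == 14
    far = detect_place_fields_1d(_map_from_rates([6] * 3 + [0] * 17),
                                 enforce_min_len=False, direction=1)
    assert len(merge_directional_fields(f_out, far)) == 2


def _gaussian_bump(shape, center, sigma, peak):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return peak * np.exp(-(((xx - center[1]) ** 2 + (yy - center[0]) ** 2)
                           / (2 * sigma ** 2)))


def _map2d(rates, bin_cm=2.0):
    edges = [np.arange(rates.shape[0] + 1) * bin_cm,
             np.arange(rates.shape[1] + 1) * bin_cm]
    return RateMap(edges, np.ones_like(rates), rates, rates, bin_cm, 0.0, 5.0)


def test_2d_field_detection_and_multipeak_split():
    single = _map2d(_gaussian_bump((40, 40), (20, 20), 4, 10.0))
    fields = detect_place_fields_2d(single)
    assert len(fields) == 1
    peak_bin = np.unravel_index(np.argmax(single.rates), single.rates.shape)
    assert any((b == peak_bin).all() for b in fields[0].bins)

    two = _map2d(_gaussian_bump((40, 40), (10, 10), 3, 10.0)
                 + _gaussian_bump((40, 40), (30, 30), 3, 10.0))
    assert len(detect_place_fields_2d(two)) == 2

    merged = _map2d(_gaussian_bump((40, 40), (18, 20), 4, 10.0)
                    + _gaussian_bump((40, 40), (30, 20), 4, 9.0))
    assert len(detect_place_fields_2d(merged, split_multipeak=False)) == 1
    assert len(detect_place_fields_2d(merged, split_multipeak=True,
                                      peak_prominence=1.0)) == 2


def test_equivalent_diameter_matches_area():
    f = PlaceField(np.zeros((0, 2), dtype=int), size=np.pi * 25.0,
                   peak_rate=5.0, center=np.zeros(2))
    assert f.equivalent_diameter() == pytest.approx(10.0)


def test_spatial_information_closed_forms():
    uniform = _map_from_rates([3.0, 3.0, 3.0, 3.0])
    assert spatial_information(uniform)[0] == pytest.approx(0.0, abs=1e-12)
    two_bin = _map_from_rates([2.0, 0.0], occupancy=[0.5, 0.5])
    bits_spike, bits_s = spatial_information(two_bin)
    assert bits_spike == pytest.approx(1.0)
    assert bits_s == pytest.approx(1.0)


def test_spatial_information_matches_direct_summation():
    rng = np.random.default_rng(30)
    rates = rng.uniform(0, 10, 50)
    occ = rng.uniform(0.1, 2.0, 50)
    rm = _map_from_rates(rates, occupancy=occ)
    p = occ / occ.sum()
    lam_bar = (p * rates).sum()
    expect = sum(pi * (li / lam_bar) * np.log2(li / lam_bar)
                 for pi, li in zip(p, rates) if li > 0)
    assert spatial_information(rm)[0] == pytest.approx(expect)


@given(st.integers(0, 10_000))
@settings(max_examples=10, deadline=None)
def test_spatial_information_nonnegative_and_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0, 8, 30)
    occ = rng.uniform(0.1, 1.0, 30)
    base = spatial_information(_map_from_rates(rates, occupancy=occ))[0]
    perm = rng.permutation(30)
    shuffled = spatial_information(_map_from_rates(rates[perm],
                                                   occupancy=occ[perm]))[0]
    assert base >= 0
    assert shuffled == pytest.approx(base)


def test_segment_entropy_closed_forms():
    assert segment_entropy(np.zeros(100)) == 0.0
    edges = np.linspace(-np.pi, np.pi, 16)
    centers = (edges[:-1] + edges[1:]) / 2
    assert segment_entropy(np.repeat(centers, 10)) == pytest.approx(
        np.log2(15))
    rng = np.random.default_rng(31)
    angles = rng.uniform(-np.pi, np.pi, 500)
    counts, _ = np.histogram(angles, bins=15, range=(-np.pi, np.pi))
    p = counts[counts > 0] / 500
    assert segment_entropy(angles) == pytest.approx(-(p * np.log2(p)).sum())
    with pytest.raises(ValueError):
        segment_entropy([])


def test_familiarity_from_a_constant_speed_run():
    """0.5 m/s constant run: familiarity = 2 s per meter."""
    n = 8000
    times = np.arange(n) * 0.025
    pos = (times * 50.0)[:, None]  # 50 cm/s? no - use 0.5 m/s = 50 cm/s
    pos = (times * 50.0)[:, None]
    traj = Trajectory(times, pos, 10_000.0)
    f = PlaceField(np.arange(10), size=40.0, peak_rate=5.0,
                   center=np.array([120.0]))
    spikes = [np.array([2.3])]  # fires inside the field pass
    stats, fields = familiarity_and_first_pass([f], spikes, [0], traj,
                                               segment_len_cm=100.0)
    assert len(fields) == 1
    assert fields[0].first_pass_speed == pytest.approx(50.0, rel=0.05)
    assert stats[0].familiarity_s_per_m == pytest.approx(2.0, rel=0.05)


def test_field_without_a_spiking_pass_is_excluded():
    n = 4000
    times = np.arange(n) * 0.025
    traj = Trajectory(times, (times * 50.0)[:, None], 10_000.0)
    f = PlaceField(np.arange(10), size=40.0, peak_rate=5.0,
                   center=np.array([120.0]))
    stats, fields = familiarity_and_first_pass(
        [f], [np.array([90.0])], [0], traj)  # spike long after the pass
    assert fields == []
    assert stats == []
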