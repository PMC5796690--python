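"""Occupancy/rate maps, spatial coherence and firing statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psfglm import (
    GroundTruthCell,
    classify_place_cell,
    compute_coherence,
    compute_rate_map,
    firing_stats,
    peak_rate,
    select_bandwidth_cv,
    simulate_spike_train,
    speed_filter,
)
from psfglm.maps import RateMap, compute_occupancy
from psfglm.synthetic import TrajectorySample


def _traj_with_speeds(speeds):
    n = len(speeds)
    t = np.arange(n, dtype=float)
    return TrajectorySample(
        t=t, x=np.zeros(n), y=np.zeros(n), speed=np.asarray(speeds, float)
    )


def _place_cell(width=10.0, alpha0=np.log(5.0), alpha1=1.5):
    return GroundTruthCell(
        field_centers=[[5.0, -3.0]],
        field_widths=[width],
        field_gains=[1.0],
        psf_beta=np.zeros(11),
        alpha0=alpha0,
        alpha1=alpha1,
        profile="flat",
    )


class TestSpeedFilter:
    def test_threshold_inclusive_boundary(self):
        traj = _traj_with_speeds([4.9, 5.0, 5.1])
        assert speed_filter(traj, 5.0).tolist() == [False, True, True]

    def test_all_fast(self):
        assert speed_filter(_traj_with_speeds([10.0] * 4), 5.0).all()

    def test_zero_threshold_passes_everything(self):
        assert speed_filter(_traj_with_speeds([0.0, 1.0]), 0.0).all()


class TestOccupancy:
    def test_total_time_equals_filtered_duration(self, arena, traj120):
        occ = compute_occupancy(traj120, arena, speed_threshold=5.0)
        n_fast = int(speed_filter(traj120, 5.0).sum())
        assert occ.total_time == pytest.approx(n_fast * traj120.dt)
        assert np.all(occ.grid >= 0)


class TestRateMap:
    def test_zero_spikes_give_zero_rate(self, arena, traj120):
        rm = compute_rate_map(np.array([]), traj120, arena=arena)
        assert np.nanmax(rm.rate) == 0.0

    def test_single_spike_mass_conserved(self, arena, traj120):
        # one spike: rate x smoothed occupancy must integrate back to 1 spike
        t_spk = np.array([traj120.t[len(traj120.t) // 2]])
        rm = compute_rate_map(t_spk, traj120, bandwidth=2.5, arena=arena,
                              occupancy_floor=0.0)
        mass = np.nansum(
            np.where(np.isfinite(rm.rate), rm.rate, 0.0) * rm.smoothed_occupancy
        )
        assert mass == pytest.approx(1.0, rel=1e-3)

    def test_rate_linear_in_spike_count(self, arena, traj120, basis):
        cell = _place_cell()
        train = simulate_spike_train(traj120, cell, basis, seed=3)
        st_ = train.spike_times
        rm1 = compute_rate_map(st_, traj120, arena=arena)
        rm2 = compute_rate_map(np.sort(np.concatenate([st_, st_])), traj120, arena=arena)
        np.testing.assert_allclose(rm2.rate, 2.0 * rm1.rate, rtol=1e-9)

    def test_zero_occupancy_errors(self, arena):
        traj = _traj_with_speeds([1.0] * 10)  # all below the speed threshold
        with pytest.raises(ValueError):
            compute_rate_map(np.array([1.0]), traj, arena=arena)


class TestBandwidthCV:
    def test_single_candidate_returned(self, traj120):
        assert select_bandwidth_cv(np.array([1.0, 2.0]), traj120, [7.5]) == 7.5

    def test_homogeneous_noise_selects_largest(self, arena, traj900, basis):
        cell = GroundTruthCell(
            field_centers=[[0, 0]], field_widths=[10], field_gains=[0],
            psf_beta=np.zeros(11), alpha0=np.log(3.0), alpha1=0.0, profile="flat",
        )
        train = simulate_spike_train(traj900, cell, basis, seed=4)
        cands = [2.5, 5.0, 10.0, 20.0, 40.0]
        bw = select_bandwidth_cv(train.spike_times, traj900, cands, arena=arena)
        assert bw == 40.0

    def test_wide_field_recovered_near_truth(self, arena, traj900, basis):
        cell = _place_cell(width=10.0, alpha0=np.log(5.0), alpha1=1.5)
        train = simulate_spike_train(traj900, cell, basis, seed=5)
        cands = [2.5, 5.0, 10.0, 20.0, 40.0]
        bw = select_bandwidth_cv(train.spike_times, traj900, cands, arena=arena)
        # the CV optimum trades smoothing against the 10-cm intrinsic width
        assert bw in (5.0, 10.0)


class TestCoherence:
    def test_checkerboard_negative_matches_brute_force(self):
        rate = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        rm = RateMap.from_array(rate)
        r = compute_coherence(rm, fisher_z=False)
        vals, nbrs = [], []
        for i in range(4):
            for j in range(4):
                acc = [
                    rate[i + di, j + dj]
                    for di in (-1, 0, 1)
                    for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0) and 0 <= i + di < 4 and 0 <= j + dj < 4
                ]
                vals.append(rate[i, j])
                nbrs.append(np.mean(acc))
        oracle = np.corrcoef(vals, nbrs)[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)
        assert r < 0

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        rate = rng.random((8, 8))
        z1 = compute_coherence(RateMap.from_array(rate))
        z2 = compute_coherence(RateMap.from_array(scale * rate))
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_smooth_bump_beats_permuted(self, arena, traj120, basis):
        cell = _place_cell()
        train = simulate_spike_train(traj120, cell, basis, seed=6)
        rm = compute_rate_map(train.spike_times, traj120, arena=arena)
        z = compute_coherence(rm)
        rng = np.random.default_rng(2)
        valid = np.isfinite(rm.rate)
        perms = []
        for _ in range(30):
            shuffled = rm.rate.copy()
            shuffled[valid] = rng.permutation(rm.rate[valid])
            perms.append(compute_coherence(RateMap.from_array(shuffled)))
        assert z > np.quantile(perms, 0.99)

    def test_shuffled_map_near_zero(self):
        rng = np.random.default_rng(3)
        vals = [
            compute_coherence(RateMap.from_array(rng.random((10, 10))))
            for _ in range(20)
        ]
        # i.i.d. pixels: coherence fluctuates around 0 at the 1/sqrt(n) scale
        assert abs(np.mean(vals)) < 3.0 / np.sqrt(100)

    def test_constant_map_undefined(self):
        with pytest.raises(ValueError):
            compute_coherence(RateMap.from_array(np.full((5, 5), 2.0)))

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError):
            compute_coherence(RateMap.from_array(np.ones((2, 2))))


class TestClassification:
    @pytest.mark.parametrize(
        "coherence,expected",
        [(0.30, True), (0.145, False), (0.256, False), (0.31, True)],
    )
    def test_threshold_inclusive(self, coherence, expected):
        assert classify_place_cell(coherence) is expected

    def test_undefined_coherence_propagates(self):
        with pytest.raises(ValueError):
            classify_place_cell(float("nan"))


class TestPeakRate:
    def test_constant_map(self):
        assert peak_rate(RateMap.from_array(np.full((5, 5), 2.0))) == 2.0

    def test_isolated_peak_averaged_with_neighbors(self):
        rate = np.zeros((5, 5))
        rate[2, 2] = 9.0
        assert peak_rate(RateMap.from_array(rate)) == pytest.approx(1.0)

    def test_matches_exhaustive_scan(self, rng):
        rate = rng.random((12, 12))
        rm = RateMap.from_array(rate)
        best = -np.inf
        for i in range(12):
            for j in range(12):
                if rate[i, j] == rate.max():
                    block = rate[max(i - 1, 0) : i + 2, max(j - 1, 0) : j + 2]
                    best = max(best, block.mean())
        assert peak_rate(rm) == pytest.approx(best)


class TestFiringStats:
    def test_mean_rate(self, traj120):
        st_ = np.linspace(1, 100, 240)
        fs = firing_stats(st_, traj120)
        assert fs.mean_rate == pytest.approx(240 / traj120.duration)

    def test_instantaneous_freq_regular_train(self, traj120):
        st_ = np.arange(0.0, 100.0, 0.1)
        fs = firing_stats(st_, traj120)
        assert fs.instantaneous_freq == pytest.approx(10.0)

    def test_instantaneous_freq_doublet_mode(self, traj120):
        # 8.5-ms doublets dominate the ISI histogram -> the 8-9 ms bin wins
        starts = np.arange(0.5, 100.0, 0.9)
        st_ = np.sort(np.concatenate([starts, starts + 0.0085]))
        fs = firing_stats(st_, traj120)
        assert fs.instantaneous_freq == pytest.approx(125.0)

    def test_too_few_spikes(self, traj120):
        assert firing_stats(np.array([1.0]), traj120).instantaneous_freq is None

    def test_coverage_bounds(self, arena, traj900):
        fs = firing_stats(np.array([1.0, 2.0, 3.0]), traj900, arena=arena)
        assert 0.0 <= fs.coverage <= 1.0
        assert fs.coverage > 0.5  # a 15-min session samples most of the arena
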