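import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcehist import (
    VoxelTimeCourse,
    compute_dps,
    compute_mws,
    detect_inflow,
    normalize_to_baseline,
    slope_maps,
)
from dcehist.exceptions import ConfigurationError, InvalidVoxelError, NoInflowError


def _tc(enh, dt=10.0):
    enh = np.asarray(enh, dtype=float)
    return VoxelTimeCourse(enh, np.arange(enh.size) * dt)


def _brute_force_mws(enh, times, inflow, window):
    """Independent oracle: exhaustive search over eligible consecutive pairs."""
    best = None
    for i in range(len(enh) - 1):
        j = i + 1
        if j >= inflow and times[j] <= times[inflow] + window:
            diff = enh[j] - enh[i]
            if best is None or diff > best[0]:
                best = (diff, j)
    return best


class TestNormalize:
    def test_percent_of_baseline(self):
        tc = normalize_to_baseline([100, 100, 100, 120], 3)
        np.testing.assert_allclose(tc.enhancement, [0, 0, 0, 20])

    def test_scale_invariance(self):
        a = normalize_to_baseline([100, 100, 100, 120], 3).enhancement
        b = normalize_to_baseline([200, 200, 200, 240], 3).enhancement
        np.testing.assert_allclose(a, b)

    def test_zero_baseline_flags_voxel_invalid(self):
        with pytest.raises(InvalidVoxelError):
            normalize_to_baseline([0, 0, 0, 10], 3)


class TestDetectInflow:
    def test_noiseless_jump_detected_at_first_post_baseline_frame(self, uniform_series):
        series = uniform_series([100, 100, 100, 130, 150, 160])
        assert detect_inflow(series) == 3

    def test_flat_trace_has_no_inflow(self, uniform_series):
        with pytest.raises(NoInflowError):
            detect_inflow(uniform_series([100, 100, 100, 100, 100]))

    def test_first_crossing_of_k_sigma_threshold(self, uniform_series):
        # baseline mean 100, SD 1 -> threshold 103; 103 does not cross, 103.5 does
        trace = [99.0, 100.0, 101.0, 102.0, 103.0, 103.5, 104.0]
        series = uniform_series(trace)
        # oracle: linear scan for the first strict crossing
        thr = 100.0 + 3.0 * 1.0
        expected = next(i for i in range(3, len(trace)) if trace[i] > thr)
        assert detect_inflow(series, k_sigma=3.0) == expected == 5


class TestComputeMws:
    def test_max_sequential_difference_within_window(self):
        mws, term = compute_mws(_tc([0, 0, 0, 12, 20, 24, 25]), inflow_index=3, window_s=30)
        assert mws == 12.0 and term == 3  # pair straddling the onset is eligible

    def test_constant_post_inflow_gives_zero(self):
        # enhancement flat through the whole eligibility window -> mws = 0
        assert compute_mws(_tc([5, 5, 5, 5, 5]), 1, 30)[0] == 0.0
        # but a jump at the onset pair itself is eligible and wins
        assert compute_mws(_tc([0, 5, 5, 5, 5]), 1, 30)[0] == 5.0

    def test_homogeneous_of_degree_one(self):
        enh = [0, 0, 0, 12, 20, 24, 25]
        m1, t1 = compute_mws(_tc(enh), 3, 30)
        m2, t2 = compute_mws(_tc(np.array(enh) * 2.0), 3, 30)
        assert m2 == pytest.approx(2 * m1) and t1 == t2

    def test_tie_takes_earliest_pair(self):
        mws, term = compute_mws(_tc([0, 0, 0, 4, 8, 12, 12]), 3, 30)
        assert mws == 4.0 and term == 3

    def test_window_shorter_than_frame_interval_is_error(self):
        # with inflow at frame 0 there is no straddling pair, so a window
        # shorter than one frame interval leaves no eligible pair at all
        with pytest.raises(ConfigurationError):
            compute_mws(_tc([0, 1, 2, 3, 4]), 0, window_s=5.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(-50, 150), min_size=6, max_size=25),
        st.integers(min_value=2, max_value=4),
        st.floats(min_value=10, max_value=100),
    )
    def test_matches_exhaustive_pair_search(self, enh, inflow, window):
        tc = _tc(enh)
        expected = _brute_force_mws(enh, tc.times_s, inflow, window)
        if expected is None:
            return
        mws, term = compute_mws(tc, inflow, window)
        assert mws == expected[0]

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-50, 150), min_size=8, max_size=25))
    def test_window_monotonicity(self, enh):
        tc = _tc(enh)
        small, _ = compute_mws(tc, 3, 20.0)
        large, _ = compute_mws(tc, 3, 100.0)
        assert large >= small


class TestComputeDps:
    def test_exact_linear_tail_both_modes(self):
        tc = _tc([0, 0, 0, 12, 14, 16, 18, 20])
        assert compute_dps(tc, 3, "two_point") == pytest.approx(2.0)
        assert compute_dps(tc, 3, "ols") == pytest.approx(2.0)

    def test_constant_tail_is_zero(self):
        tc = _tc([0, 0, 0, 7, 7, 7, 7])
        assert compute_dps(tc, 3) == 0.0

    def test_noisy_tail_two_point_vs_hand_least_squares(self):
        tc = _tc([0, 0, 0, 12, 20, 10, 18, 16])
        assert compute_dps(tc, 3, "two_point") == pytest.approx(1.0)
        # hand least squares on y = [12, 20, 10, 18, 16], x = 0..4:
        # slope = sum((x - 2)(y - 15.2)) / sum((x - 2)^2) = 6.0 / 10 = 0.6
        assert compute_dps(tc, 3, "ols") == pytest.approx(0.6)

    def test_terminal_at_last_frame_is_missing(self):
        assert np.isnan(compute_dps(_tc([0, 0, 0, 5]), 3))


class TestSlopeMaps:
    def test_uniform_phantom_gives_spatially_constant_maps(self, uniform_series):
        series = uniform_series([100, 100, 100, 130, 140, 145, 150, 152])
        maps = slope_maps(series)
        assert np.unique(maps.mws).size == 1
        assert np.unique(maps.dps).size == 1
        assert np.unique(maps.mws_terminal_index).size == 1

    def test_two_kinetic_classes_give_two_regions(self, uniform_series):
        series = uniform_series([100, 100, 100, 130, 140, 145, 150, 152])
        signal = series.signal.copy()
        signal[1] = np.broadcast_to(
            np.array([100, 100, 100, 160.0, 180, 185, 190, 191]), signal[1].shape
        )
        series2 = type(series)(signal, series.frame_times_s, series.voxel_spacing_mm, 3)
        maps = slope_maps(series2)
        assert np.unique(maps.mws).size == 2
        assert np.unique(maps.mws[0]).size == 1 and np.unique(maps.mws[1]).size == 1

    def test_map_voxel_equals_scalar_pipeline(self, uniform_series):
        rng = np.random.default_rng(42)
        series = uniform_series([100, 100, 100, 130, 140, 145, 150, 152])
        signal = series.signal + rng.normal(0, 2, series.signal.shape)
        series = type(series)(signal, series.frame_times_s, series.voxel_spacing_mm, 3)
        maps = slope_maps(series, dps_mode="ols")
        inflow = detect_inflow(series)
        vox = (1, 2, 3)
        tc = normalize_to_baseline(signal[vox], 3, series.frame_times_s)
        mws, term = compute_mws(tc, inflow, 30.0)
        assert maps.mws[vox] == pytest.approx(mws)
        assert maps.mws_terminal_index[vox] == term
        assert maps.dps[vox] == pytest.approx(compute_dps(tc, term, "ols"))

    def test_raw_mode_is_offset_invariant(self, uniform_series):
        series = uniform_series([100, 100, 100, 130, 140, 145, 150, 152])
        shifted = type(series)(
            series.signal + 500.0, series.frame_times_s, series.voxel_spacing_mm, 3
        )
        m1 = slope_maps(series, normalization="raw")
        m2 = slope_maps(shifted, normalization="raw")
        np.testing.assert_allclose(m1.mws, m2.mws)
        np.testing.assert_allclose(m1.dps, m2.dps)

    def test_invalid_voxels_are_missing(self, uniform_series):
        series = uniform_series([100, 100, 100, 130, 140, 145, 150, 152])
        signal = series.signal.copy()
        signal[0, 0, 0, :] = 0.0  # zero baseline -> invalid voxel
        series = type(series)(signal, series.frame_times_s, series.voxel_spacing_mm, 3)
        maps = slope_maps(series)
        assert np.isnan(maps.mws[0, 0, 0]) and np.isnan(maps.dps[0, 0, 0])
        assert maps.mws_terminal_index[0, 0, 0] == -1

    def test_no_inflow_propagates(self, uniform_series):
        with pytest.raises(NoInflowError):
            slope_maps(uniform_series([100, 100, 100, 100, 100, 100]))
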