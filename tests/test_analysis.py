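"""ROI statistics: normalisation, switch averaging, masks, Dice, maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from o17mri import (
    GridSpec,
    RegionTimeCourse,
    baseline_cv,
    dice,
    exclude_ventricle_margin,
    mean_around_switch,
    mirror_mask,
    normalize_to_baseline,
    relative_increase_map,
    roi_contrast,
    roi_mean_series,
)
from o17mri.recon import ImageFrame, ImageSeries


def _series(frames_data, voxel=7.5, duration=60.0):
    n = frames_data[0].shape[0]
    grid = GridSpec((n,) * 3, voxel)
    frames = tuple(
        ImageFrame(
            data=np.asarray(d, dtype=float), grid=grid,
            t_start_s=i * duration, t_end_s=(i + 1) * duration, n_projections=1,
        )
        for i, d in enumerate(frames_data)
    )
    return ImageSeries(frames=frames, frame_duration_s=duration)


def _tc(values, duration=60.0):
    values = np.asarray(values, dtype=float)
    times = duration * (np.arange(values.size) + 0.5)
    return RegionTimeCourse(region="r", values=values, frame_times_s=times)


class TestRoiMeanSeries:
    def test_uniform_frames_return_their_value(self):
        series = _series([np.full((8, 8, 8), c) for c in (1.0, 2.5, 3.0)])
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        tc = roi_mean_series(series, mask)
        assert np.allclose(tc.values, [1.0, 2.5, 3.0])

    def test_single_voxel_mask_traces_that_voxel(self):
        rng = np.random.default_rng(0)
        data = [np.abs(rng.normal(size=(8, 8, 8))) for _ in range(4)]
        series = _series(data)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3, 4, 5] = True
        tc = roi_mean_series(series, mask)
        assert np.allclose(tc.values, [d[3, 4, 5] for d in data])

    def test_checkerboard_half_mask_matches_voxel_loop(self):
        rng = np.random.default_rng(1)
        data = np.abs(rng.normal(size=(8, 8, 8)))
        series = _series([data])
        idx = np.indices((8, 8, 8)).sum(axis=0)
        mask = idx % 2 == 0
        tc = roi_mean_series(series, mask)
        total, count = 0.0, 0
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    if (i + j + k) % 2 == 0:
                        total += data[i, j, k]
                        count += 1
        assert tc.values[0] == pytest.approx(total / count)

    def test_empty_mask_rejected(self):
        series = _series([np.ones((8, 8, 8))])
        with pytest.raises(ValueError, match="empty"):
            roi_mean_series(series, np.zeros((8, 8, 8), dtype=bool))


class TestNormalizeToBaseline:
    def test_constant_series_becomes_ones(self):
        rel = normalize_to_baseline(_tc([2.0] * 6), 5)
        assert np.allclose(rel.values, 1.0)
        assert rel.normalized

    def test_hand_computed_example(self):
        rel = normalize_to_baseline(_tc([2, 2, 2, 2, 2, 3]), 5)
        assert np.allclose(rel.values, [1, 1, 1, 1, 1, 1.5])

    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale):
        raw = np.array([2.0, 2.1, 1.9, 2.0, 2.05, 2.6, 2.9])
        a = normalize_to_baseline(_tc(raw), 5)
        b = normalize_to_baseline(_tc(scale * raw), 5)
        assert np.allclose(a.values, b.values)

    def test_bad_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_baseline(_tc([1.0, 2.0]), 5)
        with pytest.raises(ValueError):
            normalize_to_baseline(_tc([0.0, 0.0, 0.0, 0.0, 0.0, 1.0]), 5)


class TestMeanAroundSwitch:
    def test_constant_series(self):
        assert mean_around_switch(_tc([1.18] * 30), 660.0, 5) == pytest.approx(1.18)

    def test_linear_ramp_returns_centre_frame_value(self):
        values = np.linspace(1.0, 2.0, 30)
        tc = _tc(values)
        # switch at 660 s starts frame 11 (mid-time 690 s)
        assert mean_around_switch(tc, 660.0, 5) == pytest.approx(values[11])

    def test_tie_goes_to_the_frame_containing_the_switch(self):
        tc = _tc(np.arange(30.0))
        # mid-times 630 and 690 are equidistant from 660; the frame
        # covering [660, 720) wins
        assert mean_around_switch(tc, 660.0, 1) == pytest.approx(11.0)

    def test_window_must_fit(self):
        with pytest.raises(ValueError, match="outside"):
            mean_around_switch(_tc([1.0, 1.0, 1.0]), 30.0, 5)


class TestBaselineCv:
    def test_constant_series_has_zero_cv(self):
        assert baseline_cv(_tc([3.3] * 8), 5) == 0.0

    def test_hand_computed_sample_sd_convention(self):
        # sd = sqrt(0.008/4) = 0.0447214, mean = 1.02 -> 4.384%
        assert baseline_cv(_tc([1, 1, 1, 1, 1.1]), 5) == pytest.approx(4.384, abs=1e-3)

    @given(scale=st.floats(0.1, 30.0))
    def test_scale_invariance(self, scale):
        raw = np.array([1.0, 1.05, 0.97, 1.01, 1.04, 2.0])
        assert baseline_cv(_tc(raw), 5) == pytest.approx(
            baseline_cv(_tc(scale * raw), 5)
        )

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            baseline_cv(_tc([1.0, 1.0]), 1)


class TestMasksOps:
    def test_mirror_is_an_involution(self):
        rng = np.random.default_rng(2)
        mask = rng.random((9, 8, 7)) > 0.5
        assert np.array_equal(mirror_mask(mirror_mask(mask)), mask)
        assert mirror_mask(mask).sum() == mask.sum()

    def test_plane_symmetric_mask_is_fixed(self):
        mask = np.zeros((9, 8, 8), dtype=bool)
        mask[2:7, 3:5, 3:5] = True  # symmetric about index 4 of axis 0
        assert np.array_equal(mirror_mask(mask), mask)

    def test_single_voxel_reflection_index(self):
        mask = np.zeros((10, 6, 6), dtype=bool)
        mask[2, 3, 4] = True
        out = mirror_mask(mask)
        assert out[10 - 1 - 2, 3, 4]
        assert out.sum() == 1

    def test_exclusion_reproduces_hand_traced_dilation(self):
        """1D toy embedded in 3D: roi {3..8}, ventricle {0,1}, two
        6-connected dilations remove {0..3} leaving {4..8}."""
        shape = (12, 7, 7)
        roi = np.zeros(shape, dtype=bool)
        roi[3:9, 3, 3] = True
        vent = np.zeros(shape, dtype=bool)
        vent[0:2, 3, 3] = True
        out = exclude_ventricle_margin(roi, vent, 2)
        expected = np.zeros(shape, dtype=bool)
        expected[4:9, 3, 3] = True
        assert np.array_equal(out, expected)

    def test_zero_dilations_is_plain_subtraction(self):
        roi = np.zeros((8, 8, 8), dtype=bool)
        roi[2:6, 2:6, 2:6] = True
        vent = np.zeros_like(roi)
        vent[2, 2, 2] = True
        out = exclude_ventricle_margin(roi, vent, 0)
        assert out.sum() == roi.sum() - 1

    def test_distant_roi_untouched(self):
        roi = np.zeros((16, 8, 8), dtype=bool)
        roi[10:13, 3:5, 3:5] = True
        vent = np.zeros_like(roi)
        vent[0:2, 3:5, 3:5] = True
        out = exclude_ventricle_margin(roi, vent, 2)
        assert np.array_equal(out, roi)

    def test_empty_result_warns_but_passes(self, caplog):
        roi = np.zeros((8, 8, 8), dtype=bool)
        roi[1, 1, 1] = True
        vent = np.zeros_like(roi)
        vent[1, 1, 2] = True
        with caplog.at_level("WARNING"):
            out = exclude_ventricle_margin(roi, vent, 2)
        assert not out.any()
        assert any("empty" in r.message for r in caplog.records)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[5, 5, 5] = True
        assert dice(a, b) == 0.0

    def test_partial_overlap_arithmetic(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, :2] = a[0, 1, :2] = a[0, 2, :2] = a[0, 3, :2] = True  # 8 voxels
        b[0, 0, :2] = b[0, 1, :2] = b[0, 2, :2] = True
        b[1, 0, :2] = True  # 8 voxels, 6 shared
        assert dice(a, b) == pytest.approx(0.75)

    def test_both_empty_is_an_error(self):
        empty = np.zeros((6, 6, 6), dtype=bool)
        with pytest.raises(ValueError):
            dice(empty, empty)

    @given(seed=st.integers(0, 100))
    def test_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6, 6)) > 0.6
        b = rng.random((6, 6, 6)) > 0.6
        if not (a.any() or b.any()):
            return
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


class TestIncreaseMapAndContrast:
    def _frame(self, data):
        n = data.shape[0]
        return ImageFrame(
            data=data, grid=GridSpec((n,) * 3, 7.5),
            t_start_s=0.0, t_end_s=180.0, n_projections=9,
        )

    def test_equal_conditions_give_zero_map(self):
        base = np.ones((8, 8, 8))
        out = relative_increase_map(self._frame(base), self._frame(base.copy()), 2)
        assert np.nanmax(np.abs(out)) < 1e-9

    def test_twenty_percent_increase_everywhere(self):
        base = np.full((8, 8, 8), 2.0)
        end = 1.2 * base
        out = relative_increase_map(self._frame(base), self._frame(end), 2)
        ok = ~np.isnan(out)
        assert ok.any()
        assert np.allclose(out[ok], 0.2, atol=1e-9)

    def test_low_baseline_voxels_are_masked(self):
        base = np.full((8, 8, 8), 4.0)
        base[0, 0, 0] = 1e-6
        out = relative_increase_map(
            self._frame(base), self._frame(base * 1.1), zero_fill_factor=1
        )
        assert np.isnan(out[0, 0, 0])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            relative_increase_map(
                self._frame(np.ones((8, 8, 8))),
                ImageFrame(
                    data=np.ones((10, 10, 10)), grid=GridSpec((10,) * 3, 7.5),
                    t_start_s=0, t_end_s=1, n_projections=1,
                ),
            )

    def test_contrast_of_printed_roi_means(self):
        # 1.158 vs 1.168 -> 0.9% deficit under the ratio definition
        assert roi_contrast(1.158, 1.168) == pytest.approx(0.9, abs=0.05)
        assert round(roi_contrast(1.158, 1.168), 1) == 0.9

    def test_equal_rois_have_zero_contrast(self):
        assert roi_contrast(1.18, 1.18) == 0.0

    def test_antisymmetry_to_first_order(self):
        c1 = roi_contrast(1.158, 1.168)
        c2 = roi_contrast(1.168, 1.158)
        # the residual is second order: |c1 + c2| = c1^2/100 / (1 - c1/100)
        assert c1 + c2 == pytest.approx(0.0, abs=c1 * c1 / 50)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            roi_contrast(0.0, 1.0)
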