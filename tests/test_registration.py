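import numpy as np
import pytest

from boldperf import (FrameTransform, ROIMask, extract_roi_curve,
                      fit_dynamic_maps, generate_phantom_series,
                      register_frames, transform_roi)
from boldperf.errors import DegenerateROIError, InputError
from boldperf.imageops import normalized_cross_correlation, shift_image
from boldperf.phantom import GASTROCNEMIUS, default_phantom_geometry

from conftest import make_subject


@pytest.fixture()
def short_series(geometry, schedule):
    """Noiseless 10-frame series (trimmed for registration speed)."""
    subject = make_subject()
    series, _ = generate_phantom_series(geometry, subject, schedule)
    series.data = series.data[:, :, :, :10]
    series.frame_times_s = series.frame_times_s[:10]
    return series


class TestRegisterFrames:
    def test_motion_free_series_gives_zero_shifts(self, short_series):
        transforms = register_frames(short_series, search_radius=3)
        assert all(t.shift == (0, 0) for t in transforms)
        assert transforms[0].frame_index == 0

    def test_known_shift_is_recovered_inverted(self, geometry, schedule):
        # content moved by (+2, -1) at frame k -> aligning shift (-2, +1)
        motion = [(0, 0)] * 10
        motion[4] = (2, -1)
        subject = make_subject(motion=motion + [(0, 0)] * 196)
        series, _ = generate_phantom_series(geometry, subject, schedule)
        series.data = series.data[:, :, :, :10]
        series.frame_times_s = series.frame_times_s[:10]
        transforms = register_frames(series, search_radius=3)
        assert transforms[4].shift == (-2, 1)
        assert all(t.shift == (0, 0) for i, t in enumerate(transforms)
                   if i != 4)

    def test_exhaustive_shift_recovery(self, geometry, schedule):
        # every shift within the search window is recovered exactly
        radius = 2
        shifts = [(dr, dc) for dr in range(-radius, radius + 1)
                  for dc in range(-radius, radius + 1)]
        motion = [(0, 0)] + shifts
        subject = make_subject(motion=motion + [(0, 0)] * (206 - len(motion)))
        series, _ = generate_phantom_series(geometry, subject, schedule)
        series.data = series.data[:, :, :, :len(motion)]
        series.frame_times_s = series.frame_times_s[:len(motion)]
        transforms = register_frames(series, search_radius=radius)
        for (dr, dc), t in zip(shifts, transforms[1:]):
            assert t.shift == (-dr, -dc)

    def test_invariant_to_global_intensity_scaling(self, short_series):
        ref = register_frames(short_series, search_radius=2)
        short_series.data[:, :, :, 5] *= 3.7
        scaled = register_frames(short_series, search_radius=2)
        assert [t.shift for t in ref] == [t.shift for t in scaled]

    def test_negative_radius_rejected(self, short_series):
        with pytest.raises(InputError):
            register_frames(short_series, search_radius=-1)


class TestNCC:
    def test_flat_image_correlates_zero(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        assert normalized_cross_correlation(np.ones((8, 8)), img) == 0.0

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8))
        assert normalized_cross_correlation(img, img) == pytest.approx(1.0)


class TestTransformROI:
    def test_identity(self, geometry):
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        out = transform_roi(roi, FrameTransform(0, (0, 0)))
        np.testing.assert_array_equal(out.mask, roi.mask)

    def test_inverse_composition_restores_mask(self, geometry):
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        fwd = transform_roi(roi, FrameTransform(1, (3, -2)))
        back = transform_roi(fwd, FrameTransform(1, (-3, 2)))
        np.testing.assert_array_equal(back.mask, roi.mask)

    def test_interior_roi_conserves_pixel_count(self, geometry):
        # exhaustive over shifts within the default search radius
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        for dr in range(-5, 6):
            for dc in range(-5, 6):
                out = transform_roi(roi, FrameTransform(0, (dr, dc)))
                assert out.pixel_count == roi.pixel_count

    def test_fully_out_of_bounds_raises(self, geometry):
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        with pytest.raises(DegenerateROIError):
            transform_roi(roi, FrameTransform(0, (40, 0)))

    def test_clinical_size_warning_only_on_full_matrix(self):
        small = np.zeros((128, 119), dtype=bool)
        small[5:8, 5:8] = True  # 9 pixels, far below 700
        with pytest.warns(UserWarning):
            ROIMask(small, "gastrocnemius")
        ok = np.zeros((128, 119), dtype=bool)
        ok[30:62, 30:62] = True  # 1024 pixels, inside [700, 1600]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            ROIMask(ok, "gastrocnemius")


class TestExtractCurve:
    def test_homogeneous_region_gives_constant_baseline_curve(
            self, geometry, schedule):
        subject = make_subject(gas=dict(baseline=24.6, overshoot=0.0,
                                        ttp=48.0))
        series, _ = generate_phantom_series(geometry, subject, schedule)
        maps = fit_dynamic_maps(series, mask=geometry.tissue_mask)
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        curve = extract_roi_curve(maps, roi, None, series.frame_times_s,
                                  series.schedule)
        rest = curve.times < series.schedule.occlusion_start
        assert np.allclose(curve.values[rest], 24.6, rtol=1e-9)

    def test_single_pixel_roi_equals_pixel_trace(self, geometry, schedule,
                                                 noiseless_subject):
        series, _ = generate_phantom_series(geometry, noiseless_subject,
                                            schedule)
        maps = fit_dynamic_maps(series, mask=geometry.tissue_mask)
        r, c = np.argwhere(geometry.mask(GASTROCNEMIUS))[0]
        mask = np.zeros(geometry.image_shape, dtype=bool)
        mask[r, c] = True
        curve = extract_roi_curve(maps, ROIMask(mask, "gastrocnemius"), None,
                                  series.frame_times_s, series.schedule)
        np.testing.assert_allclose(curve.values, maps.t2star[r, c, :])

    def test_curve_equals_brute_force_mean(self, geometry, schedule):
        subject = make_subject(noise_sigma=2.0)
        series, _ = generate_phantom_series(
            geometry, subject, schedule, rng=np.random.default_rng(5))
        maps = fit_dynamic_maps(series, mask=geometry.tissue_mask)
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        curve = extract_roi_curve(maps, roi, None, series.frame_times_s,
                                  series.schedule)
        for k in (0, 50, 205):
            use = roi.mask & maps.valid[:, :, k]
            assert curve.values[k] == pytest.approx(
                maps.t2star[:, :, k][use].mean(), rel=1e-12)
            assert curve.n_valid_pixels[k] == use.sum()

    def test_permutation_invariance_over_roi_pixels(self, geometry, schedule,
                                                    noiseless_subject):
        # the mean does not depend on pixel enumeration order: compare the
        # ROI mean with the mean over a shuffled index list
        series, _ = generate_phantom_series(geometry, noiseless_subject,
                                            schedule)
        maps = fit_dynamic_maps(series, mask=geometry.tissue_mask)
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        curve = extract_roi_curve(maps, roi, None, series.frame_times_s,
                                  series.schedule)
        idx = np.argwhere(roi.mask)
        rng = np.random.default_rng(3)
        rng.shuffle(idx)
        shuffled = np.array([maps.t2star[r, c, 10] for r, c in idx]).mean()
        assert curve.values[10] == pytest.approx(shuffled, rel=1e-12)

    def test_motion_corrected_curve_equals_motion_free(self, geometry,
                                                       schedule):
        # registration + ROI propagation exactly undoes integer motion
        rng = np.random.default_rng(8)
        n_frames = 206
        motion = [(0, 0)] + [(int(rng.integers(-2, 3)),
                              int(rng.integers(-2, 3)))
                             for _ in range(n_frames - 1)]
        still = make_subject()
        moving = make_subject(motion=motion)
        s_still, _ = generate_phantom_series(geometry, still, schedule)
        s_moving, _ = generate_phantom_series(geometry, moving, schedule)
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        maps_still = fit_dynamic_maps(s_still, mask=geometry.tissue_mask)
        maps_moving = fit_dynamic_maps(s_moving)
        transforms = register_frames(s_moving, search_radius=3)
        c_still = extract_roi_curve(maps_still, roi, None,
                                    s_still.frame_times_s, s_still.schedule)
        c_corr = extract_roi_curve(maps_moving, roi, transforms,
                                   s_moving.frame_times_s, s_moving.schedule)
        np.testing.assert_allclose(c_corr.values, c_still.values, rtol=1e-9)

    def test_zero_valid_pixels_names_the_frame(self, geometry, schedule,
                                               noiseless_subject):
        series, _ = generate_phantom_series(geometry, noiseless_subject,
                                            schedule)
        maps = fit_dynamic_maps(series, mask=geometry.tissue_mask)
        maps.valid[:, :, 3] = False
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        with pytest.raises(DegenerateROIError, match="frame 3"):
            extract_roi_curve(maps, roi, None, series.frame_times_s,
                              series.schedule)

    def test_transform_count_mismatch_rejected(self, geometry, schedule,
                                               noiseless_subject):
        series, _ = generate_phantom_series(geometry, noiseless_subject,
                                            schedule)
        maps = fit_dynamic_maps(series, mask=geometry.tissue_mask)
        roi = ROIMask(geometry.mask(GASTROCNEMIUS), "gastrocnemius")
        with pytest.raises(InputError):
            extract_roi_curve(maps, roi, [FrameTransform(0, (0, 0))],
                              series.frame_times_s, series.schedule)
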