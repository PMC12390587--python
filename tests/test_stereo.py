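"""Stereo rectification, disparity matching and view alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from handvein.stereo import (
    DisparityMap,
    MatchingParams,
    PinholeView,
    StereoCalibration,
    _rectifying_rotations,
    align_view,
    compute_disparity,
    depth_to_disparity,
    disparity_to_depth,
    rectify_pair,
)
from handvein.synth import render_stereo_pair

K = np.array([[300.0, 0, 159.5], [0, 300.0, 119.5], [0, 0, 1.0]])
SIZE = (240, 320)


def _calib(rotvec=(0, 0, 0), translation=(-60.0, 0, 0), dist=0.0):
    return StereoCalibration(
        K_left=K,
        K_right=K,
        dist_left=np.full(5, dist),
        dist_right=np.full(5, dist),
        rotation=Rotation.from_rotvec(rotvec).as_matrix(),
        translation_mm=np.array(translation),
        image_size=SIZE,
    )


class TestDisparityDepth:
    def test_reference_geometry(self):
        # 4 mm lens over 3.4 um pixels at 120 mm working distance
        f_px = 4.0 / 0.0034
        d = depth_to_disparity(120.0, 50.0, f_px)
        assert d == pytest.approx(490.2, abs=0.05)
        assert disparity_to_depth(d, 50.0, f_px) == pytest.approx(120.0)

    def test_reciprocal_law(self):
        z1 = disparity_to_depth(10.0, 50.0, 1000.0)
        z2 = disparity_to_depth(20.0, 50.0, 1000.0)
        assert z1 == pytest.approx(2 * z2)

    def test_round_trip_identity(self, rng):
        z = rng.uniform(50, 500, 1000)
        back = disparity_to_depth(depth_to_disparity(z, 48.0, 1176.5), 48.0, 1176.5)
        np.testing.assert_allclose(back, z, rtol=1e-12)

    def test_non_positive_disparity_flagged(self):
        assert np.isnan(disparity_to_depth(0.0, 50.0, 1000.0))
        with pytest.raises(ValueError):
            DisparityMap(
                disparity=np.full((4, 4), -1.0),
                valid=np.ones((4, 4), bool),
                focal_length_px=1000.0,
            )


class TestRectification:
    def test_identity_configuration_is_identity_resampling(self, rng):
        img = rng.random(SIZE)
        left, right, rect = rectify_pair(img, img.copy(), _calib())
        interior = np.s_[5:-5, 5:-5]
        np.testing.assert_allclose(left[interior], img[interior], atol=1e-6)
        assert rect.baseline_mm == pytest.approx(60.0)

    @pytest.mark.parametrize("rotvec", [(0, np.deg2rad(5), 0), (0.03, -0.05, 0.02)])
    def test_epipolar_row_alignment_after_rotation(self, rotvec, rng):
        calib = _calib(rotvec=rotvec)
        Rl, Rr = _rectifying_rotations(calib)
        X = np.stack(
            [rng.uniform(-60, 60, 50), rng.uniform(-45, 45, 50), rng.uniform(150, 400, 50)],
            axis=1,
        )
        Xl = X @ Rl.T
        Xr = (X @ calib.rotation.T + calib.translation_mm) @ Rr.T
        rows_l = 300.0 * Xl[:, 1] / Xl[:, 2]
        rows_r = 300.0 * Xr[:, 1] / Xr[:, 2]
        assert np.abs(rows_l - rows_r).max() <= 0.5

    def test_row_alignment_over_random_calibrations(self, rng):
        """Randomized small rotations and distortions keep epipolar rows
        aligned for the ideal (distortion-free) projection model."""
        for _ in range(100):
            calib = _calib(
                rotvec=rng.uniform(-0.17, 0.17, 3),
                translation=np.array([-60.0, 0, 0]) + rng.uniform(-5, 5, 3) * [0, 1, 1],
            )
            Rl, Rr = _rectifying_rotations(calib)
            X = np.stack(
                [rng.uniform(-50, 50, 20), rng.uniform(-40, 40, 20), rng.uniform(150, 400, 20)],
                axis=1,
            )
            Xl = X @ Rl.T
            Xr = (X @ calib.rotation.T + calib.translation_mm) @ Rr.T
            misalign = 300.0 * np.abs(Xl[:, 1] / Xl[:, 2] - Xr[:, 1] / Xr[:, 2])
            assert misalign.max() <= 0.5

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            rectify_pair(np.zeros((50, 50)), np.zeros((50, 50)), _calib())

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            StereoCalibration(K, K, np.zeros(5), np.zeros(5), np.eye(3) * 1.1,
                              [-60, 0, 0], SIZE)


class TestDisparityMatching:
    def test_pure_integer_shift(self, rng):
        left = rng.random((120, 200))
        left = np.repeat(np.repeat(left[::2, ::2], 2, 0), 2, 1)  # add texture scale
        k = 7
        right = np.roll(left, -k, axis=1)
        dm = compute_disparity(left, right, MatchingParams(max_disparity=20))
        median = np.median(dm.disparity[dm.valid])
        assert abs(median - k) <= 0.5

    def test_dot_scene_median_error_below_one_pixel(self):
        z = np.full((160, 240), 120.0)
        left, right, d_true = render_stereo_pair(z, baseline_mm=6.0, focal_px=800, seed=1)
        dm = compute_disparity(left, right, MatchingParams(max_disparity=60))
        err = np.abs(dm.disparity[dm.valid] - d_true[dm.valid])
        assert np.median(err) <= 1.0
        assert dm.valid.mean() > 0.5

    def test_slanted_plane_slope_recovery(self):
        yy, xx = np.mgrid[0:160, 0:240]
        slope_true = 0.08
        z = 100.0 + slope_true * xx
        left, right, d_true = render_stereo_pair(z, baseline_mm=6.0, focal_px=800, seed=2)
        dm = compute_disparity(left, right, MatchingParams(max_disparity=60))
        m = dm.valid & (dm.disparity > 0)
        z_rec = disparity_to_depth(dm.disparity[m], 6.0, 800)
        A = np.stack([xx[m], np.ones(m.sum())], axis=1)
        coef = np.linalg.lstsq(A, z_rec, rcond=None)[0]
        resid = np.abs(z_rec - A @ coef)
        keep = resid < 5 * np.median(resid)  # clip gross outliers, refit
        slope = np.linalg.lstsq(A[keep], z_rec[keep], rcond=None)[0][0]
        assert abs(slope - slope_true) / slope_true <= 0.05

    def test_untextured_input_mostly_invalid_with_warning(self):
        flat = np.full((80, 80), 0.5)
        with pytest.warns(UserWarning, match="untextured|matched"):
            dm = compute_disparity(flat, flat.copy(), MatchingParams(max_disparity=20))
        assert dm.valid.mean() < 0.1


class TestAlignView:
    def test_identity_camera_is_identity(self, rng):
        depth = np.full((60, 80), 150.0)
        src = rng.random((60, 80))
        Kr = np.array([[100.0, 0, 39.5], [0, 100.0, 29.5], [0, 0, 1]])
        out, holes = align_view(src, depth, PinholeView(K=Kr), Kr)
        inner = np.s_[2:-2, 2:-2]
        np.testing.assert_allclose(out[inner], src[inner], atol=1e-6)

    def test_lateral_offset_gives_constant_shift(self):
        depth = np.full((60, 80), 200.0)
        src = np.zeros((60, 80))
        src[:, 40] = 1.0
        Kr = np.array([[100.0, 0, 39.5], [0, 100.0, 29.5], [0, 0, 1]])
        # src camera 20 mm to the right: shift = f * tx / z = 100*20/200 = 10 px
        view = PinholeView(K=Kr, T=np.array([20.0, 0, 0]))
        out, _ = align_view(src, depth, view, Kr)
        cols = np.nanargmax(out, axis=1)
        assert np.median(cols) == pytest.approx(30, abs=1)

    def test_invalid_depth_becomes_flagged_holes(self):
        depth = np.full((20, 20), np.nan)
        out, holes = align_view(np.ones((20, 20)), depth, PinholeView(K=K), K)
        assert holes == 400
        assert np.isnan(out).all()
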