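"""Synthetic generator determinism, ground-truth consistency, realism knobs."""

import numpy as np
import pytest

from handvein.synth import (
    CANVAS_SHAPE,
    RenderParams,
    corner_lights,
    make_identity,
    render_hand,
    render_ps_quad,
    render_stereo_pair,
)


class TestIdentities:
    def test_seed_determinism(self):
        a = make_identity(0)
        b = make_identity(0)
        for fa, fb in zip(a.fingers, b.fingers):
            assert fa.center_x == fb.center_x and fa.length_px == fb.length_px
            for ba, bb in zip(fa.branches, fb.branches):
                np.testing.assert_array_equal(ba.points_xy, bb.points_xy)

    def test_different_seeds_differ(self):
        a, b = make_identity(0), make_identity(1)
        assert any(
            fa.branches[0].points_xy.shape != fb.branches[0].points_xy.shape
            or not np.array_equal(fa.branches[0].points_xy, fb.branches[0].points_xy)
            for fa, fb in zip(a.fingers, b.fingers)
        )

    def test_vein_branch_counts(self):
        for seed in range(5):
            for finger in make_identity(seed).fingers:
                assert 3 <= len(finger.branches) <= 8

    def test_vein_nodes_inside_finger(self):
        for finger in make_identity(3).fingers:
            half = finger.width_px / 2
            for branch in finger.branches:
                assert (np.abs(branch.points_xy[:, 0]) <= 0.9 * half).all()
                assert (branch.points_xy[:, 1] <= finger.base_y).all()


class TestHandRender:
    def test_bit_identical_reruns(self):
        identity = make_identity(5)
        a = render_hand(identity, sample_seed=2)
        b = render_hand(identity, sample_seed=2)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.applied_rotation_deg == b.applied_rotation_deg

    def test_zero_jitter_zero_noise_is_pose_free(self):
        params = RenderParams(
            rotation_jitter_deg=0.0, translation_jitter_px=0, gain_jitter=0.0,
            illumination_gradient=0.0, noise_sigma=0.0,
        )
        identity = make_identity(6)
        a = render_hand(identity, params, sample_seed=0)
        b = render_hand(identity, params, sample_seed=9)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.applied_rotation_deg == 0.0

    def test_foreground_background_separation(self):
        """Across seeds, tissue/background contrast dwarfs the noise level."""
        for seed in range(20):
            render = render_hand(make_identity(40 + seed), sample_seed=seed)
            img = render.image.astype(float) / 1023.0
            fg = img[render.silhouette].mean()
            bg = img[~render.silhouette].mean()
            assert fg - bg >= 5 * RenderParams().noise_sigma

    def test_vein_centerlines_are_intensity_valleys(self):
        render = render_hand(make_identity(11), sample_seed=0)
        img = render.image.astype(float)
        tissue_median = np.median(img[render.silhouette])
        vals = []
        for pts in render.vein_centerlines:
            xi = np.round(pts[:, 0]).astype(int)
            yi = np.round(pts[:, 1]).astype(int)
            ok = (
                (xi >= 0) & (xi < CANVAS_SHAPE[1]) & (yi >= 0) & (yi < CANVAS_SHAPE[0])
            )
            vals.append(img[yi[ok], xi[ok]].mean())
        assert all(v < tissue_median for v in vals)

    def test_ground_truth_masks_cover_four_fingers(self):
        render = render_hand(make_identity(12), sample_seed=1)
        assert render.finger_labels == ["index", "middle", "ring", "little"]
        assert len(render.finger_masks) == 4
        for mask in render.finger_masks:
            assert mask.any()


class TestStereoGenerator:
    def test_constant_depth_constant_disparity(self):
        z = np.full((60, 90), 150.0)
        _, _, d = render_stereo_pair(z, baseline_mm=6.0, focal_px=500)
        assert np.allclose(d, 6.0 * 500 / 150.0)

    def test_slanted_plane_linear_ramp(self):
        yy, xx = np.mgrid[0:60, 0:90]
        z = 100.0 + 0.5 * xx
        _, _, d = render_stereo_pair(z, baseline_mm=6.0, focal_px=500)
        col_means = d.mean(axis=0)
        diffs = np.diff(1.0 / col_means)  # 1/d linear in z hence in x
        assert np.allclose(diffs, diffs[0], rtol=1e-6)

    def test_excessive_disparity_rejected(self):
        with pytest.raises(ValueError, match="disparity"):
            render_stereo_pair(np.full((40, 40), 1.0), baseline_mm=50.0, focal_px=1000)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            render_stereo_pair(np.zeros((10, 10)))


class TestPsGenerator:
    def test_plane_under_symmetric_lights_equal_means(self):
        normals = np.zeros((40, 40, 3))
        normals[..., 2] = 1.0
        frames, _, _ = render_ps_quad(normals, corner_lights())
        means = frames.mean(axis=(1, 2))
        assert np.allclose(means, means[0], rtol=1e-12)

    def test_zero_albedo_region_propagates(self):
        normals = np.zeros((30, 30, 3))
        normals[..., 2] = 1.0
        albedo = np.ones((30, 30))
        albedo[:10] = 0.0
        frames, _, _ = render_ps_quad(normals, corner_lights(), albedo=albedo)
        assert (frames[:, :10] == 0).all()

    def test_rank_deficient_lights_rejected(self):
        bad = np.array([[1.0, 0, 0], [0, 1, 0], [1, 1, 0], [-1, 1, 0]])
        bad = bad / np.linalg.norm(bad, axis=1, keepdims=True)
        with pytest.raises(ValueError, match="rank"):
            render_ps_quad(np.zeros((5, 5, 3)), bad)


class TestDifficultyKnobs:
    def test_harder_conditions_degrade_scores(self):
        """Lower vein contrast plus more noise monotonically shrinks the
        genuine/impostor margin, averaged over seeds."""
        from handvein.matching import match_templates
        from handvein.pipeline import build_templates

        levels = [
            RenderParams(),
            RenderParams(vein_contrast=0.15, noise_sigma=0.02),
            RenderParams(vein_contrast=0.08, noise_sigma=0.04),
        ]
        margins = []
        for params in levels:
            gaps = []
            for seed in (0, 1, 2):
                ia = make_identity(500 + seed, "RH")
                ib = make_identity(600 + seed, "RH")
                ta0 = build_templates(render_hand(ia, params, 0).image, "RH")
                ta1 = build_templates(render_hand(ia, params, 1).image, "RH")
                tb0 = build_templates(render_hand(ib, params, 0).image, "RH")
                if None in (ta0, ta1, tb0):
                    gaps.append(0.0)
                    continue
                genuine = np.mean(
                    [match_templates(ta0[f], ta1[f]).score for f in ("index", "middle", "ring")]
                )
                impostor = np.mean(
                    [match_templates(ta0[f], tb0[f]).score for f in ("index", "middle", "ring")]
                )
                gaps.append(genuine - impostor)
            margins.append(np.mean(gaps))
        assert margins[0] > margins[1] > margins[2]
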