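"""Finger extraction, anatomical reordering and rotation normalization."""

import numpy as np
import pytest

from handvein.segmentation import (
    EmptyMaskError,
    FingerImage,
    OrderingError,
    SegmentationResult,
    extract_fingers,
    finger_axis_angle_deg,
    foreground_mask,
    normalize_finger,
    reorder_fingers,
)
from handvein.synth import make_identity, render_hand, rotate_image


def _bar_image(columns, height=120, width=200, top_offsets=None, bar_width=20):
    """Bright vertical bars on a dark background."""
    img = np.full((height, width), 10, np.uint16)
    tops = top_offsets or [0] * len(columns)
    for cx, top in zip(columns, tops):
        img[top : height - 5, cx - bar_width // 2 : cx + bar_width // 2] = 600
    return img


class TestForegroundMask:
    def test_bimodal_image_splits_on_brightness(self):
        img = np.full((50, 50), 10, np.uint16)
        img[:, 25:] = 200
        mask = foreground_mask(img, opening_radius=0)
        assert mask[:, 25:].all() and not mask[:, :25].any()

    def test_small_specks_removed_by_opening(self):
        img = np.full((80, 80), 10, np.uint16)
        img[10:70, 30:50] = 600
        img[5:8, 5:8] = 600  # 3 px speck
        mask = foreground_mask(img, opening_radius=5)
        assert not mask[5:8, 5:8].any()
        assert mask[40, 40]

    def test_constant_image_rejected(self):
        with pytest.raises(EmptyMaskError):
            foreground_mask(np.full((30, 30), 42, np.uint16))

    def test_hand_render_silhouette_dice(self, rendered_hand):
        mask = foreground_mask(rendered_hand.image)
        truth = rendered_hand.silhouette
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.98


class TestExtractFingers:
    def test_four_bars_tips_recovered_in_height_order(self):
        tops = [30, 0, 10, 20]
        img = _bar_image([30, 75, 120, 165], top_offsets=tops)
        result = extract_fingers(img)
        assert result.complete
        # extraction order is by tip height; verify via recorded crops
        crop_tops = sorted(f.crop_origin[0] for f in result.fingers)
        assert crop_tops == sorted(max(t - 5, 0) for t in tops)

    def test_three_bars_incomplete_not_error(self):
        img = _bar_image([40, 90, 140])
        result = extract_fingers(img)
        assert not result.complete
        assert len(result.fingers) == 3

    def test_empty_image_empty_result(self):
        img = np.full((60, 60), 10, np.uint16)
        img[2:9, 2:9] = 600  # only a small blob, removed as non-finger
        result = extract_fingers(img)
        assert len(result.fingers) == 0

    def test_synthetic_hand_masks_match_truth(self, rendered_hand):
        result = extract_fingers(rendered_hand.image)
        assert result.complete
        ordered = reorder_fingers(result, "RH")
        for finger, truth in zip(ordered.fingers, rendered_hand.finger_masks):
            full = np.zeros_like(truth)
            r0, c0 = finger.crop_origin
            full[r0 : r0 + finger.mask.shape[0], c0 : c0 + finger.mask.shape[1]] = finger.mask
            iou = (full & truth).sum() / (full | truth).sum()
            assert iou >= 0.9

    def test_foreground_conserved_by_peeling(self, rendered_hand):
        mask = foreground_mask(rendered_hand.image)
        result = extract_fingers(rendered_hand.image, mask=mask)
        total = np.zeros_like(mask)
        for finger in result.fingers:
            r0, c0 = finger.crop_origin
            sub = total[r0 : r0 + finger.mask.shape[0], c0 : c0 + finger.mask.shape[1]]
            assert not (sub & finger.mask).any()  # fingers are disjoint
            sub |= finger.mask
        assert (total & ~mask).sum() == 0  # fingers within original foreground


class TestReorder:
    def _result(self, centroids):
        fingers = []
        for cx in centroids:
            mask = np.zeros((30, 10), bool)
            mask[5:25, 2:8] = True
            fingers.append(FingerImage(image=np.zeros((30, 10)), mask=mask,
                                       centroid_xy=(cx, 15.0)))
        return SegmentationResult(fingers=fingers)

    def test_right_hand_left_to_right(self):
        result = reorder_fingers(self._result([90, 30, 120, 60]), "RH")
        assert [f.finger_label for f in result.fingers] == ["index", "middle", "ring", "little"]
        assert [f.centroid_xy[0] for f in result.fingers] == [30, 60, 90, 120]

    def test_left_hand_reversed(self):
        result = reorder_fingers(self._result([30, 60, 90, 120]), "LH")
        assert [f.centroid_xy[0] for f in result.fingers] == [120, 90, 60, 30]

    def test_order_invariance_of_input_list(self):
        a = reorder_fingers(self._result([30, 60, 90, 120]), "RH")
        b = reorder_fingers(self._result([120, 90, 60, 30]), "RH")
        assert [f.centroid_xy[0] for f in a.fingers] == [f.centroid_xy[0] for f in b.fingers]

    def test_incomplete_rejected(self):
        with pytest.raises(OrderingError, match="four"):
            reorder_fingers(self._result([30, 60, 90]), "RH")


class TestNormalize:
    def _bar_finger(self, angle=0.0):
        img = np.full((160, 120), 20.0)
        img[20:140, 50:70] = 500.0
        if angle:
            img = rotate_image(img, angle, center_xy=(59.5, 79.5))
        mask = img > 100
        return FingerImage(image=img, mask=mask)

    def test_axis_aligned_bar_zero_rotation(self):
        out = normalize_finger(self._bar_finger())
        assert abs(out.rotation_deg) <= 0.1

    @pytest.mark.parametrize("angle", [-10.0, -4.0, 4.0, 10.0])
    def test_known_rotation_recovered(self, angle):
        out = normalize_finger(self._bar_finger(angle))
        assert out.rotation_deg == pytest.approx(-angle, abs=0.5)

    def test_idempotent(self):
        once = normalize_finger(self._bar_finger(8.0))
        twice = normalize_finger(once)
        assert abs(twice.rotation_deg - once.rotation_deg) <= 0.2

    def test_extreme_angle_rejected(self):
        mask = np.zeros((100, 100), bool)
        for i in range(60):  # diagonal bar at 45 deg
            mask[20 + i // 2, 20 + i // 1] = True
        finger = FingerImage(image=np.zeros((100, 100)), mask=mask)
        with pytest.raises(ValueError):
            normalize_finger(finger, max_angle_deg=45.0)


class TestBatchRecovery:
    def test_rotation_recovery_on_rendered_hands(self):
        """Injected whole-hand rotations come back through the midline fit."""
        errors = []
        for seed in range(8):
            identity = make_identity(300 + seed, "RH")
            render = render_hand(identity, sample_seed=seed)
            result = extract_fingers(render.image)
            if not result.complete:
                continue
            for finger in result.fingers:
                normalized = normalize_finger(finger)
                errors.append(normalized.rotation_deg - (-render.applied_rotation_deg))
        assert len(errors) >= 24
        assert np.max(np.abs(errors)) <= 0.5
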