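"""Finger segmentation: isolate up to four fingers from a hand image,
order them anatomically and rotation-normalize each one.

The hand is bright on a dark background (NIR transillumination).  A
foreground mask is produced by Otsu thresholding plus morphological
opening.  Fingers are then peeled off one at a time: the topmost
foreground row marks the tip of the tallest remaining finger, whose
boundary is traced row-by-row downward until the traced run widens
abruptly (the palm junction); the traced region is erased and the
procedure repeats, up to four times.  Because extraction order is by tip
height, the fingers are subsequently reordered by the x-coordinate of
their mask centroids, which is only well-defined when all four fingers
were found — incomplete hands are excluded from recognition experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from skimage.transform import rotate as _rotate

FINGER_LABELS = ("index", "middle", "ring", "little")


class EmptyMaskError(ValueError):
    pass


class OrderingError(RuntimeError):
    """Anatomical labels cannot be assigned (fewer than four fingers)."""


@dataclass
class FingerImage:
    """A cropped, mask-carrying single-finger image."""

    image: np.ndarray
    mask: np.ndarray
    finger_label: str = "unknown"
    rotation_deg: float = 0.0
    centroid_xy: tuple[float, float] = (0.0, 0.0)  # source-image coordinates
    crop_origin: tuple[int, int] = (0, 0)  # (row, col) of crop in source

    def __post_init__(self) -> None:
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError("mask/image shape mismatch")
        if not self.mask.any():
            raise EmptyMaskError("finger mask is empty")
        if abs(self.rotation_deg) > 45:
            raise ValueError("|rotation_deg| must be <= 45")


@dataclass
class SegmentationResult:
    fingers: list[FingerImage] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return len(self.fingers) == 4


@dataclass
class SegmentationParams:
    opening_radius: int = 5
    width_stop_factor: float = 1.8
    min_trace_rows: int = 12  # rows traced before the width stop can fire
    min_finger_rows: int = 20
    crop_pad: int = 5


def foreground_mask(image: np.ndarray, opening_radius: int = 5) -> np.ndarray:
    """Otsu threshold plus opening with a disk structuring element."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if img.max() == img.min():
        raise EmptyMaskError("constant image: no foreground/background contrast")
    thresh = threshold_otsu(img)
    mask = img > thresh
    if opening_radius > 0:
        mask = opening(mask, disk(opening_radius))
    if not mask.any():
        raise EmptyMaskError("foreground mask is empty after opening")
    return mask


def _row_runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) spans of True runs in a boolean row."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], row.view(np.uint8), [0]])))
    return [(int(idx[i]), int(idx[i + 1] - 1)) for i in range(0, len(idx), 2)]


def _trace_finger(work: np.ndarray, params: SegmentationParams):
    """Trace the tallest remaining finger from its tip downward.

    Returns the traced boolean mask, or None if nothing is left.  The run
    containing the tip column is followed down; 8-connectivity is
    emulated by letting the followed span grow by one pixel per side when
    matching runs in the next row.  Tracing stops at the bottom of the
    mask, when continuity breaks, or when the run width exceeds
    ``width_stop_factor`` times the running median width (the palm).
    """
    rows_any = np.flatnonzero(work.any(axis=1))
    if len(rows_any) == 0:
        return None
    top = int(rows_any[0])
    runs = _row_runs(work[top])
    # tallest finger's tip: the widest run in the topmost row
    span = max(runs, key=lambda r: r[1] - r[0])
    traced = np.zeros_like(work)
    widths: list[int] = []
    for r in range(top, work.shape[0]):
        candidates = [
            (a, b)
            for a, b in _row_runs(work[r])
            if b >= span[0] - 1 and a <= span[1] + 1
        ]
        if not candidates:
            break
        a = min(c[0] for c in candidates)
        b = max(c[1] for c in candidates)
        width = b - a + 1
        if len(widths) >= params.min_trace_rows:
            if width > params.width_stop_factor * float(np.median(widths)):
                break
        traced[r, a : b + 1] = work[r, a : b + 1]
        widths.append(width)
        span = (a, b)
    return traced if traced.any() else None


def extract_fingers(
    image: np.ndarray,
    params: SegmentationParams | None = None,
    mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Segment up to four fingers from a hand image.

    Fewer than four detected fingers is not an error: the result simply
    has ``complete == False`` and downstream protocol construction
    excludes the sample.
    """
    if params is None:
        params = SegmentationParams()
    if mask is None:
        try:
            mask = foreground_mask(image, params.opening_radius)
        except EmptyMaskError:
            return SegmentationResult(fingers=[])
    work = mask.copy()
    fingers: list[FingerImage] = []
    attempts = 0
    while len(fingers) < 4 and attempts < 12:
        attempts += 1
        # drop boundary crumbs left over from previous erasures
        lab, n = ndimage.label(work)
        if n:
            sizes = np.bincount(lab.ravel())
            sizes[0] = 0
            work &= ~np.isin(lab, np.flatnonzero((sizes > 0) & (sizes < 200)))
        traced = _trace_finger(work, params)
        if traced is None:
            break
        work &= ~traced
        rows = np.flatnonzero(traced.any(axis=1))
        if len(rows) < params.min_finger_rows:
            continue  # too short to be a finger (e.g. knuckle remnant)
        cols = np.flatnonzero(traced.any(axis=0))
        r0 = max(int(rows[0]) - params.crop_pad, 0)
        r1 = min(int(rows[-1]) + params.crop_pad + 1, image.shape[0])
        c0 = max(int(cols[0]) - params.crop_pad, 0)
        c1 = min(int(cols[-1]) + params.crop_pad + 1, image.shape[1])
        sub_mask = traced[r0:r1, c0:c1]
        cy, cx = ndimage.center_of_mass(traced)
        fingers.append(
            FingerImage(
                image=np.asarray(image)[r0:r1, c0:c1].copy(),
                mask=sub_mask,
                centroid_xy=(float(cx), float(cy)),
                crop_origin=(r0, c0),
            )
        )
    return SegmentationResult(fingers=fingers)


def reorder_fingers(
    result: SegmentationResult, hand: str, palm_toward_camera: bool = True
) -> SegmentationResult:
    """Assign anatomical labels by centroid x-coordinate.

    With the palm facing the camera (default presentation over the
    sensor), the right hand reads index-to-little from left to right in
    the image and the left hand reads the reverse.  Requires exactly four
    fingers: with fewer, it is impossible to tell e.g. whether three
    detected fingers are index/middle/ring or middle/ring/little.
    """
    if hand not in ("LH", "RH"):
        raise ValueError("hand must be 'LH' or 'RH'")
    if not result.complete:
        raise OrderingError(
            f"cannot assign labels to {len(result.fingers)} fingers; "
            "exactly four are required for unambiguous ordering"
        )
    ordered = sorted(result.fingers, key=lambda f: f.centroid_xy[0])
    left_to_right_is_index_first = (hand == "RH") == palm_toward_camera
    labels = FINGER_LABELS if left_to_right_is_index_first else FINGER_LABELS[::-1]
    out = []
    for finger, label in zip(ordered, labels):
        out.append(
            FingerImage(
                image=finger.image,
                mask=finger.mask,
                finger_label=label,
                rotation_deg=finger.rotation_deg,
                centroid_xy=finger.centroid_xy,
                crop_origin=finger.crop_origin,
            )
        )
    out.sort(key=lambda f: FINGER_LABELS.index(f.finger_label))
    return SegmentationResult(fingers=out)


def finger_axis_angle_deg(mask: np.ndarray) -> float:
    """Angle of the finger's longitudinal axis relative to vertical.

    Least-squares line through the per-row midpoints of the mask; the
    returned angle is positive when the fingertip leans toward larger x
    (counter-clockwise in standard image display).
    """
    rows = np.flatnonzero(mask.any(axis=1))
    if len(rows) < 20:
        raise ValueError("mask must span at least 20 rows for axis estimation")
    mids = np.empty(len(rows))
    widths = np.empty(len(rows))
    for i, r in enumerate(rows):
        cols = np.flatnonzero(mask[r])
        mids[i] = 0.5 * (cols[0] + cols[-1])
        widths[i] = cols[-1] - cols[0] + 1
    # partial rows at the tip/base corners bias the midpoints; keep rows
    # near full width
    keep = widths >= 0.8 * np.median(widths)
    slope = np.polyfit(rows[keep].astype(float), mids[keep], 1)[0]  # dx/dy
    return float(np.degrees(np.arctan(slope)))


def normalize_finger(finger: FingerImage, max_angle_deg: float = 45.0) -> FingerImage:
    """Rotate a finger so its longitudinal axis is vertical.

    The axis is the least-squares midline of the mask; image and mask are
    rotated about the mask centroid by the negative of the axis angle and
    the applied angle is recorded.  Idempotent to within the midline
    estimator's resolution.
    """
    angle = finger_axis_angle_deg(finger.mask)
    if abs(angle) > max_angle_deg:
        raise ValueError(
            f"axis angle {angle:.1f} deg exceeds {max_angle_deg} deg: not a finger"
        )
    cy, cx = ndimage.center_of_mass(finger.mask)
    # the applied normalization rotation is the negative of the axis angle
    img = _rotate(
        finger.image.astype(float), -angle, center=(cx, cy), preserve_range=True, order=1
    )
    msk = (
        _rotate(finger.mask.astype(float), -angle, center=(cx, cy), preserve_range=True, order=1)
        > 0.5
    )
    # re-crop around the straightened axis so templates of the same finger
    # share a common frame; width from the median row width, which is
    # robust to residual palm flare at the trace bottom
    rows = np.flatnonzero(msk.any(axis=1))
    mids = np.empty(len(rows))
    widths = np.empty(len(rows))
    for i, r in enumerate(rows):
        cc = np.flatnonzero(msk[r])
        mids[i] = 0.5 * (cc[0] + cc[-1])
        widths[i] = cc[-1] - cc[0] + 1
    pad = 8
    center = float(np.median(mids))
    half = 0.5 * float(np.median(widths)) + pad
    c0 = max(int(round(center - half)), 0)
    c1 = min(int(round(center + half)) + 1, msk.shape[1])
    r0 = max(int(rows[0]) - 5, 0)
    r1 = min(int(rows[-1]) + 6, msk.shape[0])
    img, msk = img[r0:r1, c0:c1], msk[r0:r1, c0:c1]
    return FingerImage(
        image=img,
        mask=msk,
        finger_label=finger.finger_label,
        rotation_deg=finger.rotation_deg - angle,
        centroid_xy=finger.centroid_xy,
        crop_origin=finger.crop_origin,
    )
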