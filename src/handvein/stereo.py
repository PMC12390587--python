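"""Calibrated stereo: rectification, disparity, metric depth and cross-view
alignment for the NIR camera pair.

Geometry conventions: the left camera is the reference frame; a point with
left-frame coordinates X maps into the right camera as X' = R X + T (T in
millimetres).  For a rectified pair, a 3-D point at distance z projects to
the same row in both views with a horizontal offset — the disparity —

    d = x - x' = B f / z

with B the baseline and f the focal length in pixel units.  Disparity is
non-negative for points in front of the cameras.

The 5-coefficient distortion model (k1, k2, p1, p2, k3: radial + tangential)
is applied in normalized coordinates; rectification resamples each image so
that epipolar lines become horizontal and aligned across the views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class StereoCalibration:
    """Intrinsics and relative pose of a calibrated camera pair."""

    K_left: np.ndarray  # 3x3
    K_right: np.ndarray  # 3x3
    dist_left: np.ndarray  # (5,) k1 k2 p1 p2 k3
    dist_right: np.ndarray  # (5,)
    rotation: np.ndarray  # 3x3, right w.r.t. left
    translation_mm: np.ndarray  # (3,)
    image_size: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.K_left = np.asarray(self.K_left, dtype=float)
        self.K_right = np.asarray(self.K_right, dtype=float)
        self.dist_left = np.asarray(self.dist_left, dtype=float).reshape(5)
        self.dist_right = np.asarray(self.dist_right, dtype=float).reshape(5)
        R = np.asarray(self.rotation, dtype=float)
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-8 or abs(np.linalg.det(R) - 1) > 1e-8:
            raise ValueError("rotation must be orthonormal (within 1e-8)")
        self.rotation = R
        self.translation_mm = np.asarray(self.translation_mm, dtype=float).reshape(3)
        if self.baseline_mm <= 0:
            raise ValueError("baseline must be positive")
        h, w = self.image_size
        for K in (self.K_left, self.K_right):
            if not (0 <= K[0, 2] < w and 0 <= K[1, 2] < h):
                raise ValueError("principal point outside image bounds")

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.translation_mm))


@dataclass
class RectifiedCalibration:
    """Virtual pinhole pair produced by rectification: shared intrinsics,
    per-camera rectifying rotations, horizontal baseline."""

    K: np.ndarray
    R_rect_left: np.ndarray
    R_rect_right: np.ndarray
    baseline_mm: float
    image_size: tuple[int, int]

    @property
    def focal_px(self) -> float:
        return float(self.K[0, 0])


@dataclass
class DisparityMap:
    disparity: np.ndarray  # (H, W) float, pixels
    valid: np.ndarray  # (H, W) bool
    focal_length_px: float

    def __post_init__(self) -> None:
        if (self.disparity[self.valid] < 0).any():
            raise ValueError("valid disparities must be non-negative")


@dataclass
class MatchingParams:
    """Block-matching configuration (ZNCC cost, winner-take-all with
    parabolic sub-pixel refinement)."""

    min_disparity: int = 0
    max_disparity: int = 64
    block_size: int = 9
    confidence_threshold: float = 0.5  # minimum peak ZNCC for validity
    texture_threshold: float = 1e-3  # min local std (fraction of range)
    subpixel: bool = True
    lr_consistency: bool = True  # reject half-occluded pixels
    lr_threshold_px: float = 1.0


def _distort(x: np.ndarray, y: np.ndarray, dist: np.ndarray):
    """Apply the 5-coefficient model in normalized camera coordinates."""
    k1, k2, p1, p2, k3 = dist
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return xd, yd


def _rectifying_rotations(calib: StereoCalibration):
    """Shared orientation with the new x-axis along the baseline."""
    R, T = calib.rotation, calib.translation_mm
    b = -R.T @ T  # right camera centre in left coordinates
    e1 = b / np.linalg.norm(b)
    if e1[0] < 0:  # keep disparity positive for the left-reference convention
        e1 = -e1
    e2 = np.cross([0.0, 0.0, 1.0], e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R_rect = np.stack([e1, e2, e3])  # rows: new axes in old left coords
    return R_rect, R_rect @ R.T


def rectify_pair(
    left: np.ndarray, right: np.ndarray, calib: StereoCalibration
) -> tuple[np.ndarray, np.ndarray, RectifiedCalibration]:
    """Undistort and rectify a stereo pair.

    After rectification a 3-D point projects to the same row in both
    output images.  Output intrinsics are shared: focal length is the mean
    of the four input focals, principal point at the image centre.
    Out-of-view source samples become NaN.
    """
    h, w = calib.image_size
    for name, img in (("left", left), ("right", right)):
        if img.shape[:2] != (h, w):
            raise ValueError(f"{name} image shape {img.shape[:2]} != calibration {h, w}")
    Rl, Rr = _rectifying_rotations(calib)
    f_new = float(
        np.mean([calib.K_left[0, 0], calib.K_left[1, 1], calib.K_right[0, 0], calib.K_right[1, 1]])
    )
    K_new = np.array([[f_new, 0, (w - 1) / 2.0], [0, f_new, (h - 1) / 2.0], [0, 0, 1.0]])

    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    outputs = []
    for img, K, dist, R_rect in (
        (left, calib.K_left, calib.dist_left, Rl),
        (right, calib.K_right, calib.dist_right, Rr),
    ):
        # rectified pixel -> ray in rectified frame -> original camera frame
        x = (uu - K_new[0, 2]) / f_new
        y = (vv - K_new[1, 2]) / f_new
        rays = np.stack([x, y, np.ones_like(x)], axis=-1) @ R_rect  # = R^T . ray
        xn = rays[..., 0] / rays[..., 2]
        yn = rays[..., 1] / rays[..., 2]
        xd, yd = _distort(xn, yn, dist)
        src_u = K[0, 0] * xd + K[0, 2]
        src_v = K[1, 1] * yd + K[1, 2]
        out = ndimage.map_coordinates(
            np.asarray(img, dtype=float), [src_v, src_u], order=1, mode="constant", cval=np.nan
        )
        outputs.append(out)

    rect = RectifiedCalibration(K_new, Rl, Rr, calib.baseline_mm, (h, w))
    return outputs[0], outputs[1], rect


def disparity_to_depth(d_px, baseline_mm: float, focal_px: float):
    """Metric depth z = B f / d.  Non-positive disparities map to NaN."""
    d = np.asarray(d_px, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(d > 0, baseline_mm * focal_px / np.where(d > 0, d, 1.0), np.nan)
    return z if z.ndim else float(z)


def depth_to_disparity(z_mm, baseline_mm: float, focal_px: float):
    """Inverse relation d = B f / z."""
    z = np.asarray(z_mm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(z > 0, baseline_mm * focal_px / np.where(z > 0, z, 1.0), np.nan)
    return d if d.ndim else float(d)


def _zncc_volume(left: np.ndarray, right: np.ndarray, params: MatchingParams):
    """ZNCC cost volume over the disparity search range."""
    b = params.block_size
    L = np.asarray(left, dtype=float)
    R = np.asarray(right, dtype=float)
    L = np.nan_to_num(L, nan=0.0)
    R = np.nan_to_num(R, nan=0.0)

    def local_stats(img):
        m = ndimage.uniform_filter(img, b)
        sq = ndimage.uniform_filter(img * img, b)
        var = np.maximum(sq - m * m, 0.0)
        return m, np.sqrt(var)

    mL, sL = local_stats(L)
    disparities = np.arange(params.min_disparity, params.max_disparity + 1)
    vol = np.full((len(disparities), *L.shape), -np.inf)
    for i, d in enumerate(disparities):
        Rs = np.roll(R, d, axis=1)  # Rs(y, x) = R(y, x - d)
        mR, sR = local_stats(Rs)
        cross = ndimage.uniform_filter(L * Rs, b) - mL * mR
        denom = sL * sR
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(denom > 1e-12, cross / np.maximum(denom, 1e-12), -1.0)
        z[:, :d] = -np.inf  # no right-image support
        vol[i] = z
    return disparities, vol, sL


def compute_disparity(
    left_rect: np.ndarray,
    right_rect: np.ndarray,
    params: MatchingParams | None = None,
    focal_px: float = float("nan"),
) -> DisparityMap:
    """Dense disparity by ZNCC block matching with sub-pixel refinement.

    Low-confidence pixels (weak correlation peak or untextured support
    window) are flagged invalid rather than set to zero, and a left-right
    consistency check rejects half-occluded pixels.  Sub-pixel precision
    comes from a parabola fit through the cost peak and its two
    neighbours.
    """
    if params is None:
        params = MatchingParams()
    if left_rect.shape != right_rect.shape:
        raise ValueError("rectified pair must share dimensions")
    disparities, vol, texture = _zncc_volume(left_rect, right_rect, params)
    best = np.argmax(vol, axis=0)
    peak = np.take_along_axis(vol, best[None], axis=0)[0]

    disp = disparities[best].astype(float)
    if params.subpixel:
        lo = np.clip(best - 1, 0, len(disparities) - 1)
        hi = np.clip(best + 1, 0, len(disparities) - 1)
        c_lo = np.take_along_axis(vol, lo[None], axis=0)[0]
        c_hi = np.take_along_axis(vol, hi[None], axis=0)[0]
        denom = c_lo - 2 * peak + c_hi
        interior = (best > 0) & (best < len(disparities) - 1)
        ok = interior & np.isfinite(c_lo) & np.isfinite(c_hi) & (np.abs(denom) > 1e-12)
        delta = np.zeros_like(disp)
        delta[ok] = 0.5 * (c_lo[ok] - c_hi[ok]) / denom[ok]
        disp += np.clip(delta, -0.5, 0.5)

    rng = np.nanmax(left_rect) - np.nanmin(left_rect)
    valid = (
        np.isfinite(peak)
        & (peak >= params.confidence_threshold)
        & (texture >= params.texture_threshold * max(rng, 1e-12))
        & (disp >= 0)
    )
    if params.lr_consistency:
        # matching the flipped pair swaps the roles of the two cameras,
        # giving the right image's disparity under the same convention
        inner = MatchingParams(
            **{**params.__dict__, "lr_consistency": False}
        )
        disp_r = compute_disparity(
            right_rect[:, ::-1], left_rect[:, ::-1], inner
        ).disparity[:, ::-1]
        h, w = disp.shape
        cols = np.arange(w)[None, :].repeat(h, axis=0)
        xr = np.clip(np.rint(cols - disp).astype(int), 0, w - 1)
        back = np.take_along_axis(disp_r, xr, axis=1)
        valid &= np.abs(disp - back) <= params.lr_threshold_px
    if valid.mean() < 0.1:
        import warnings

        warnings.warn(
            f"only {valid.mean():.1%} of pixels matched confidently "
            "(untextured or mismatched input)",
            stacklevel=2,
        )
    disp[~valid] = 0.0
    return DisparityMap(disparity=disp, valid=valid, focal_length_px=float(focal_px))


@dataclass
class PinholeView:
    """A pinhole camera posed relative to the left rectified frame:
    X_view = R X + T (T in mm)."""

    K: np.ndarray
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    T: np.ndarray = field(default_factory=lambda: np.zeros(3))


def align_view(
    src: np.ndarray,
    depth_map: np.ndarray,
    src_view: PinholeView,
    ref_K: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Resample a source view (e.g. RGB) onto the left rectified grid.

    Each reference pixel with valid depth is back-projected to 3-D,
    transformed into the source camera and sampled bilinearly.  Pixels
    with missing depth or projecting outside the source become NaN holes;
    the hole count is returned alongside the image.
    """
    h, w = depth_map.shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    z = np.asarray(depth_map, dtype=float)
    good = np.isfinite(z) & (z > 0)

    X = np.stack(
        [(uu - ref_K[0, 2]) / ref_K[0, 0] * z, (vv - ref_K[1, 2]) / ref_K[1, 1] * z, z],
        axis=-1,
    )
    Xs = X @ src_view.R.T + src_view.T
    with np.errstate(invalid="ignore", divide="ignore"):
        us = src_view.K[0, 0] * Xs[..., 0] / Xs[..., 2] + src_view.K[0, 2]
        vs = src_view.K[1, 1] * Xs[..., 1] / Xs[..., 2] + src_view.K[1, 2]
    us = np.where(good, us, -1.0)
    vs = np.where(good, vs, -1.0)

    src_f = np.asarray(src, dtype=float)
    if src_f.ndim == 2:
        out = ndimage.map_coordinates(src_f, [vs, us], order=1, mode="constant", cval=np.nan)
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(src_f[..., c], [vs, us], order=1, mode="constant", cval=np.nan)
                for c in range(src_f.shape[-1])
            ],
            axis=-1,
        )
    hole = ~good | ~np.isfinite(out if out.ndim == 2 else out[..., 0])
    if out.ndim == 2:
        out[hole] = np.nan
    else:
        out[hole] = np.nan
    return out, int(hole.sum())
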