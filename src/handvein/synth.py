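"""Seeded synthetic data: NIR hand renders with ground-truth vein
networks, stereo pairs with known disparity, Lambertian photometric
quadruples and labeled score sets.

The hand generator emulates the fingers-closed presentation over an
upward-facing NIR camera: four roughly parallel, rounded, bright fingers
on a dark background, joined by a palm at the bottom, with per-identity
curvilinear dark vein networks (random branching trees confined to each
finger).  An identity fixes geometry and vein topology; per-sample
variation is limited to pose jitter (whole-hand rotation and
translation), photometric jitter (gain, smooth illumination gradient)
and sensor noise — mirroring the genuine/impostor structure a
verification experiment assumes.  Every generator is a pure function of
its seeds and returns ground truth alongside the rendered data.

No attempt is made at photorealism or at modeling 850 vs 950 nm
penetration physics; wavelength is a label on synthetic channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import rotate as _sk_rotate

CANVAS_SHAPE = (420, 340)  # portrait: fingertips toward the top edge
FINGER_LABELS = ("index", "middle", "ring", "little")


# ---------------------------------------------------------------------------
# geometry helpers shared with tests

def rotate_image(image: np.ndarray, angle_deg: float, center_xy=None, order=1):
    """Rotate image content by ``angle_deg`` with skimage conventions.

    A fingertip leaning toward +x is straightened by a positive angle in
    :func:`handvein.segmentation.normalize_finger`; this helper and
    :func:`rotate_points` share one convention so analytic ground truth
    matches rendered rasters.
    """
    return _sk_rotate(
        image.astype(float), angle_deg, center=center_xy, preserve_range=True, order=order
    )


def rotate_points(xy: np.ndarray, angle_deg: float, center_xy) -> np.ndarray:
    """Map (x, y) points the same way ``rotate_image`` maps content."""
    # skimage.rotate with angle a maps source coords via the inverse
    # rotation; content at source point p lands at R(-a) (p - c) + c in
    # image coordinates (y down), i.e. a clockwise rotation of the axes.
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    c = np.asarray(center_xy, dtype=float)
    return (np.asarray(xy, dtype=float) - c) @ R.T + c


# ---------------------------------------------------------------------------
# identities

@dataclass
class VeinBranch:
    points_xy: np.ndarray  # (n, 2) float, identity-canvas coordinates
    width_px: np.ndarray  # (n,) float


@dataclass
class SyntheticFinger:
    label: str
    center_x: float
    base_y: float
    length_px: float
    width_px: float
    branches: list[VeinBranch] = field(default_factory=list)


@dataclass
class SyntheticIdentity:
    seed: int
    hand: str
    fingers: list[SyntheticFinger]


@dataclass
class RenderParams:
    """Per-sample jitter and photometric conditions.

    Defaults model a cooperative presentation: a few degrees of pose
    rotation, sub-centimetre translation, modest gain drift, a smooth
    illumination gradient and 10-bit sensor noise.  Vein contrast is the
    valley depth as a fraction of the surrounding tissue intensity.
    """

    rotation_jitter_deg: float = 3.0
    translation_jitter_px: int = 8
    gain_jitter: float = 0.10
    illumination_gradient: float = 0.15
    noise_sigma: float = 0.01  # fraction of full scale
    vein_contrast: float = 0.25
    background_level: float = 0.06
    tissue_level: float = 0.55

    def __post_init__(self) -> None:
        if not 0 < self.vein_contrast < 1:
            raise ValueError("vein contrast must lie in (0, 1)")
        for name in ("rotation_jitter_deg", "translation_jitter_px", "gain_jitter",
                     "illumination_gradient", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _grow_branch(rng, x0, y0, y_top, half_width, width0, n_steps, drift):
    xs = [x0]
    ys = [y0]
    x = x0
    for _ in range(n_steps):
        y = ys[-1] - 2.0
        if y <= y_top:
            break
        x = x + rng.normal(drift, 1.0)
        x = float(np.clip(x, -0.76 * half_width, 0.76 * half_width))
        xs.append(x)
        ys.append(y)
    pts = np.stack([np.asarray(xs), np.asarray(ys)], axis=1)
    taper = np.linspace(1.0, 0.55, len(pts))
    return pts, width0 * taper


def make_identity(seed: int, hand: str = "RH") -> SyntheticIdentity:
    """Deterministic synthetic identity: four finger silhouettes with
    non-crossing branching vein trees (3-8 branches per finger)."""
    rng = np.random.default_rng(seed)
    h, w = CANVAS_SHAPE
    base_y = 330.0
    centers = np.array([55.0, 130.0, 205.0, 280.0]) + rng.uniform(-6, 6, 4)
    lengths = np.array([205.0, 235.0, 215.0, 160.0]) + rng.uniform(-12, 12, 4)
    widths = np.array([44.0, 48.0, 44.0, 38.0]) + rng.uniform(-3, 3, 4)
    # anatomical order left-to-right depends on the presented hand
    labels = FINGER_LABELS if hand == "RH" else FINGER_LABELS[::-1]

    fingers = []
    for label, cx, length, width in zip(labels, centers, lengths, widths):
        finger = SyntheticFinger(label, float(cx), base_y, float(length), float(width))
        y_top = base_y - length + width / 2 + 6
        n_branches = int(rng.integers(3, 9))
        trunk_pts, trunk_w = _grow_branch(
            rng,
            x0=float(rng.uniform(-0.2, 0.2) * width / 2),
            y0=base_y - 4,
            y_top=y_top,
            half_width=width / 2,
            width0=float(rng.uniform(3.6, 4.6)),
            n_steps=int(length),
            drift=0.0,
        )
        finger.branches.append(VeinBranch(trunk_pts, trunk_w))
        for _ in range(n_branches - 1):
            j = int(rng.integers(len(trunk_pts) // 4, len(trunk_pts) - 2))
            bx, by = trunk_pts[j]
            pts, bw = _grow_branch(
                rng,
                x0=float(bx),
                y0=float(by),
                y_top=y_top,
                half_width=width / 2,
                width0=float(rng.uniform(2.0, 3.2)),
                n_steps=int(rng.integers(25, 90)),
                drift=float(rng.choice([-0.6, 0.6])),
            )
            finger.branches.append(VeinBranch(pts, bw))
        fingers.append(finger)
    return SyntheticIdentity(seed=int(seed), hand=hand, fingers=fingers)


# ---------------------------------------------------------------------------
# hand rendering

def _finger_silhouette(finger: SyntheticFinger, shape) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    half = finger.width_px / 2
    tip_y = finger.base_y - finger.length_px + half
    # slight distal taper
    frac = np.clip((finger.base_y - yy) / max(finger.length_px, 1), 0, 1)
    half_at = half * (1.0 - 0.12 * frac)
    shaft = (
        (np.abs(xx - finger.center_x) <= half_at)
        & (yy >= tip_y)
        & (yy <= finger.base_y)
    )
    cap = ((xx - finger.center_x) / (half * 0.88)) ** 2 + (
        (yy - tip_y) / half
    ) ** 2 <= 1.0
    return shaft | (cap & (yy < tip_y))


def _vein_map(identity: SyntheticIdentity, shape) -> tuple[np.ndarray, list[np.ndarray]]:
    """Valley-depth map in [0, 1] and per-finger centerline point lists
    ((x, y) in canvas coordinates)."""
    h, w = shape
    vmap = np.zeros(shape)
    centerlines = []
    for finger in identity.fingers:
        pts_all = []
        for branch in finger.branches:
            pts = branch.points_xy.copy()
            pts[:, 0] += finger.center_x  # local x offset -> canvas
            pts_all.append(pts)
            for (x, y), bw in zip(pts, branch.width_px):
                sigma = max(bw / 2.0, 1.0)
                r = int(np.ceil(3 * sigma))
                xi, yi = int(round(x)), int(round(y))
                y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
                x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
                if y0 >= y1 or x0 >= x1:
                    continue
                gy, gx = np.mgrid[y0:y1, x0:x1]
                d2 = (gx - x) ** 2 + (gy - y) ** 2
                patch = np.exp(-d2 / (2 * sigma**2))
                np.maximum(vmap[y0:y1, x0:x1], patch, out=vmap[y0:y1, x0:x1])
        centerlines.append(np.concatenate(pts_all, axis=0))
    return vmap, centerlines


@dataclass
class HandRender:
    """A rendered sample plus full ground truth."""

    image: np.ndarray  # uint16, 10-bit range
    silhouette: np.ndarray  # bool
    finger_masks: list[np.ndarray]  # bool, anatomical order index..little
    finger_labels: list[str]
    vein_centerlines: list[np.ndarray]  # (n, 2) (x, y) per finger
    applied_rotation_deg: float
    applied_translation_px: tuple[int, int]  # (dx, dy)
    identity: SyntheticIdentity


def render_hand(
    identity: SyntheticIdentity,
    params: RenderParams | None = None,
    sample_seed: int = 0,
    max_retries: int = 5,
) -> HandRender:
    """Render one sample of an identity with seeded jitter and noise.

    Bright hand on dark background; veins are Gaussian-profile intensity
    valleys; a multiplicative illumination field and additive Gaussian
    noise model the capture chain.  If jitter pushes a finger out of
    frame, the sample is re-jittered with a warning (bounded retries).
    """
    if params is None:
        params = RenderParams()
    shape = CANVAS_SHAPE
    h, w = shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)

    sil_parts = [_finger_silhouette(f, shape) for f in identity.fingers]
    palm = np.zeros(shape, dtype=bool)
    x_lo = int(identity.fingers[0].center_x - identity.fingers[0].width_px)
    x_hi = int(identity.fingers[-1].center_x + identity.fingers[-1].width_px)
    palm[int(identity.fingers[0].base_y) :, max(x_lo, 0) : min(x_hi, w)] = True
    vmap, centerlines = _vein_map(identity, shape)

    for attempt in range(max_retries + 1):
        rng = np.random.default_rng([int(identity.seed), int(sample_seed), attempt])
        theta = float(rng.uniform(-params.rotation_jitter_deg, params.rotation_jitter_deg))
        tj = params.translation_jitter_px
        dx, dy = (int(rng.integers(-tj, tj + 1)), int(rng.integers(-tj, tj + 1))) if tj else (0, 0)
        gain = 1.0 + float(rng.uniform(-params.gain_jitter, params.gain_jitter))
        gx = float(rng.uniform(-params.illumination_gradient, params.illumination_gradient))
        gy = float(rng.uniform(-params.illumination_gradient, params.illumination_gradient))

        def xform(img, order):
            out = rotate_image(img, theta, center_xy=center, order=order)
            return ndimage.shift(out, (dy, dx), order=0, mode="constant", cval=0.0)

        masks = [xform(p.astype(float), 0) > 0.5 for p in sil_parts]
        inside = all(
            m.any()
            and not (m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any())
            for m in masks
        )
        if inside:
            break
        if attempt == max_retries:
            raise RuntimeError("could not keep all fingers in frame after retries")
        warnings.warn("jitter pushed a finger out of frame; re-jittering", stacklevel=2)

    sil = xform((np.any(sil_parts, axis=0) | palm).astype(float), 0) > 0.5
    veins = xform(vmap, 1)
    tissue = params.tissue_level * gain
    img = np.where(sil, tissue, params.background_level)
    img = img * (1.0 - params.vein_contrast * veins * sil)
    yy, xx = np.mgrid[0:h, 0:w]
    field = 1.0 + gx * (xx - w / 2) / w + gy * (yy - h / 2) / h
    img = img * field
    img = img + rng.normal(0.0, params.noise_sigma, shape)
    img = np.clip(img, 0.0, 1.0)
    image = np.round(img * 1023).astype(np.uint16)

    moved_lines = [
        rotate_points(pts, theta, center) + np.array([dx, dy]) for pts in centerlines
    ]
    labels = [f.label for f in identity.fingers]
    order = [labels.index(lbl) for lbl in FINGER_LABELS]
    return HandRender(
        image=image,
        silhouette=sil,
        finger_masks=[masks[i] for i in order],
        finger_labels=list(FINGER_LABELS),
        vein_centerlines=[moved_lines[i] for i in order],
        applied_rotation_deg=theta,
        applied_translation_px=(dx, dy),
        identity=identity,
    )


# ---------------------------------------------------------------------------
# stereo

def render_stereo_pair(
    depth_mm: np.ndarray,
    dot_density: float = 0.02,
    baseline_mm: float = 50.0,
    focal_px: float = 1176.5,
    seed: int = 0,
    dot_sigma: float = 1.0,
):
    """Laser-dot stereo pair from a known depth map (left-camera grid).

    The left view is a random dot texture; the right view is the left
    resampled by the per-pixel disparity d = B f / z.  Returns
    (left, right, true_disparity) with disparity on the left grid.
    """
    z = np.asarray(depth_mm, dtype=float)
    if (z <= 0).any():
        raise ValueError("depth must be positive everywhere")
    h, w = z.shape
    d = baseline_mm * focal_px / z
    if d.max() >= w:
        raise ValueError(
            f"max disparity {d.max():.1f} px exceeds image width {w}; "
            "reduce baseline or increase depth"
        )
    rng = np.random.default_rng(seed)
    left = np.full((h, w), 0.08)
    n_dots = int(dot_density * h * w)
    ys = rng.integers(0, h, n_dots)
    xs = rng.integers(0, w, n_dots)
    left[ys, xs] += rng.uniform(0.6, 1.0, n_dots)
    left = ndimage.gaussian_filter(left, dot_sigma)

    # right(y, x_r) = left(y, x_r + d); d varies with the left pixel, so
    # solve the fixed point d_r(x_r) = d(x_r + d_r) by iteration
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d_r = d.copy()
    for _ in range(5):
        d_r = ndimage.map_coordinates(d, [yy, np.clip(xx + d_r, 0, w - 1)], order=1)
    right = ndimage.map_coordinates(left, [yy, xx + d_r], order=1, mode="nearest")
    return left, right, d


# ---------------------------------------------------------------------------
# photometric stereo

def corner_lights(slant: float = 0.5) -> np.ndarray:
    """Four unit light directions from the corners of the LED frame."""
    dirs = np.array(
        [[-slant, -slant, 1.0], [slant, -slant, 1.0], [-slant, slant, 1.0], [slant, slant, 1.0]]
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def sphere_normals(shape, radius_px, center=None):
    """Analytic normals of a sphere cap on a fronto-parallel plane;
    returns (normals (H,W,3), on_sphere mask)."""
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    dx = (xx - center[0]) / radius_px
    dy = (yy - center[1]) / radius_px
    r2 = dx * dx + dy * dy
    inside = r2 < 1.0
    nz = np.sqrt(np.clip(1.0 - r2, 0.0, 1.0))
    normals = np.zeros((h, w, 3))
    normals[..., 0] = np.where(inside, dx, 0.0)
    normals[..., 1] = np.where(inside, dy, 0.0)
    normals[..., 2] = np.where(inside, nz, 1.0)
    return normals, inside


def point_source_falloff(shape, height_px: float, center=None) -> np.ndarray:
    """Relative irradiance of a point source over a plane (inverse-square
    law with obliquity), normalized to peak 1."""
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    r2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + height_px**2
    irr = height_px / np.power(r2, 1.5)
    return irr / irr.max()


def render_ps_quad(
    normals: np.ndarray,
    lights: np.ndarray,
    albedo: np.ndarray | float = 1.0,
    noise_sigma: float = 0.0,
    falloff: np.ndarray | None = None,
    seed: int = 0,
):
    """Lambertian frames I_i = albedo max(0, L_i . N), with an optional
    shared illumination falloff baked into both the frames and the
    constant-albedo flat-field references.

    Returns (frames (n,H,W), flat_fields list, normals)."""
    L = np.asarray(lights, dtype=float)
    if np.linalg.matrix_rank(L) < 3:
        raise ValueError("light directions must span rank 3")
    N = np.asarray(normals, dtype=float)
    h, w = N.shape[:2]
    alb = np.broadcast_to(np.asarray(albedo, dtype=float), (h, w))
    if falloff is None:
        falloff = np.ones((h, w))
    rng = np.random.default_rng(seed)
    frames = []
    flats = []
    for li in L:
        shade = np.maximum(N @ li, 0.0)
        frame = alb * shade * falloff
        if noise_sigma > 0:
            frame = frame + rng.normal(0, noise_sigma, frame.shape)
        frames.append(frame)
        flats.append(falloff.copy())
    frames = np.stack(frames)
    shadow_frac = float((frames.max(axis=0) <= 0).mean())
    if shadow_frac > 0.5:
        warnings.warn(
            f"{shadow_frac:.0%} of pixels receive no light; check geometry",
            stacklevel=2,
        )
    return frames, flats, N


# ---------------------------------------------------------------------------
# labeled score sets

def random_score_set(
    seed: int,
    n_genuine: int = 200,
    n_impostor: int = 600,
    separation: float = 2.0,
):
    """Labeled (genuine, impostor) score samples with a controllable
    separation (difference of means in pooled-std units)."""
    rng = np.random.default_rng(seed)
    impostor = rng.normal(0.25, 0.08, n_impostor)
    genuine = rng.normal(0.25 + separation * 0.08, 0.08, n_genuine)
    return genuine, impostor
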