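"""Vein enhancement and maximum-curvature (MC) template extraction.

Under NIR illumination, hemoglobin absorption renders veins as dark,
roughly Gaussian-profile valleys in the finger image.  The MC extractor
scans the image line by line (transverse to the finger by default, plus
longitudinal and the two diagonals), computes the curvature

    kappa = P'' / (1 + P'^2)^(3/2)

of each smoothed cross-sectional profile P, and marks the curvature
maximum of every concave (valley) region with a score proportional to
kappa times the region width — wide, deep valleys score highest, and the
maximum sits at the vein centerline.  Scores accumulated over all scan
directions are reinforced along each direction by a connectivity filter
(isolated responses shrink, aligned ones grow) and binarized at the
median of the strictly positive scores.  The resulting binary map is the
biometric template.

Enhancement is a pluggable interface.  The default classical enhancer
removes slowly varying background illumination (large-kernel Gaussian
subtraction) and applies local contrast normalization inside the finger
mask; a learned autoencoder enhancer can be registered under the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .segmentation import FingerImage

DIRECTIONS = ("transverse", "longitudinal", "diagonal", "antidiagonal")


class EmptyTemplateError(ValueError):
    """No curvature response anywhere (flat input)."""


@dataclass
class VeinTemplate:
    """Binary MC feature map used as the biometric template."""

    feature_map: np.ndarray
    finger_label: str = "unknown"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        fm = np.asarray(self.feature_map).astype(bool)
        active = fm.mean()
        if fm.sum() < 1:
            raise EmptyTemplateError("template has no active pixels")
        if active > 0.30:
            raise ValueError(f"template {active:.0%} active; expected <= 30%")
        self.feature_map = fm

    @property
    def shape(self) -> tuple[int, int]:
        return self.feature_map.shape

    @property
    def n_active(self) -> int:
        return int(self.feature_map.sum())


@dataclass
class MCParams:
    """Maximum-curvature extraction settings.

    The default scans only transverse to the finger axis, where veins —
    which run roughly along the finger — present their sharpest valley
    profile; the full four-direction variant of the feature family is
    available through ``directions``.
    """

    profile_sigma_px: float = 2.0
    directions: tuple[str, ...] = ("transverse",)
    connectivity_filter: bool = True
    mask_erosion_px: int = 8  # suppress silhouette-edge and tip-cap curvature


# ---------------------------------------------------------------------------
# Enhancement

def _identity_enhancer(finger: FingerImage) -> FingerImage:
    return finger


def _baseline_enhancer(
    finger: FingerImage, background_sigma: float = 20.0
) -> FingerImage:
    """Background-illumination removal + local contrast normalization.

    The illumination field is multiplicative, so the background (a
    large-kernel Gaussian of the mask-filled image) is divided out rather
    than subtracted; boundary distortions of the smoothing cancel in the
    ratio.  The residual detail is then normalized by its local standard
    deviation inside the finger mask.
    """
    img = finger.image.astype(float)
    mask = finger.mask
    fill = img[mask].mean() if mask.any() else img.mean()
    # global illumination field: low-order polynomial fit over the mask,
    # divided out (multiplicative model); tracks ramps that a finite
    # smoothing kernel cannot follow near the crop boundary
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    yn, xn = (yy - h / 2) / max(h, 1), (xx - w / 2) / max(w, 1)
    basis = np.stack(
        [np.ones_like(xn), xn, yn, xn * yn, xn**2, yn**2], axis=-1
    )
    coef, *_ = np.linalg.lstsq(basis[mask], img[mask], rcond=None)
    field = basis @ coef
    floor = 1e-6 * max(abs(fill), 1e-12)
    flattened = np.where(mask, img / np.maximum(field, floor), 1.0)
    # mid-scale background removal + local contrast normalization
    background = gaussian_filter(flattened, background_sigma)
    detail = flattened - background
    local_sd = np.sqrt(
        np.maximum(gaussian_filter(detail**2, background_sigma), 0.0)
    )
    enhanced = detail / np.maximum(local_sd, 1e-6)
    enhanced = np.where(mask, enhanced, 0.0)
    return FingerImage(
        image=enhanced,
        mask=mask,
        finger_label=finger.finger_label,
        rotation_deg=finger.rotation_deg,
        centroid_xy=finger.centroid_xy,
        crop_origin=finger.crop_origin,
    )


ENHANCERS: dict[str, Callable[[FingerImage], FingerImage]] = {
    "identity": _identity_enhancer,
    "baseline": _baseline_enhancer,
}


def register_enhancer(name: str, fn: Callable[[FingerImage], FingerImage]) -> None:
    """Register an enhancement backend (e.g. a learned model wrapper)."""
    ENHANCERS[name] = fn


def enhance_veins(finger: FingerImage, method: str = "baseline") -> FingerImage:
    if method not in ENHANCERS:
        raise KeyError(
            f"unknown enhancer {method!r}; available: {sorted(ENHANCERS)}"
        )
    return ENHANCERS[method](finger)


# ---------------------------------------------------------------------------
# Maximum curvature

def _score_profiles(profiles: np.ndarray, valid: np.ndarray, sigma: float) -> np.ndarray:
    """Curvature scores for a batch of scan lines.

    For each line, each maximal run of positive profile curvature (a
    valley region) deposits kappa_max * run_width at the position of the
    curvature maximum.
    """
    n, L = profiles.shape
    # replicate the nearest valid value into invalid positions so that a
    # mask edge behaves exactly like the array edge (translation covariance)
    rows = np.arange(n)[:, None]
    fwd = np.maximum.accumulate(np.where(valid, np.arange(L)[None, :], -1), axis=1)
    bwd = np.minimum.accumulate(
        np.where(valid, np.arange(L)[None, :], L)[:, ::-1], axis=1
    )[:, ::-1]
    z = np.where(
        fwd >= 0,
        profiles[rows, np.clip(fwd, 0, L - 1)],
        profiles[rows, np.clip(bwd, 0, L - 1)],
    )
    z[~valid.any(axis=1)] = 0.0
    z = gaussian_filter1d(z, sigma, axis=1, mode="nearest")
    p1 = np.gradient(z, axis=1)
    p2 = np.gradient(p1, axis=1)
    kappa = p2 / np.power(1.0 + p1 * p1, 1.5)

    pos = (kappa > 0) & valid
    # separate lines with a guard column, then label runs on the flat array
    guard = np.zeros((n, 1), dtype=bool)
    flat_pos = np.concatenate([pos, guard], axis=1).ravel()
    flat_kappa = np.concatenate([kappa, np.zeros((n, 1))], axis=1).ravel()
    starts = flat_pos & ~np.concatenate([[False], flat_pos[:-1]])
    run_id = np.cumsum(starts) * flat_pos  # 0 outside runs
    if run_id.max() == 0:
        return np.zeros_like(profiles)
    widths = np.bincount(run_id)[1:]
    # argmax of kappa within each run via lexsort (kappa ascending per run)
    order = np.lexsort((flat_kappa, run_id))
    sorted_runs = run_id[order]
    boundaries = np.flatnonzero(np.diff(np.append(sorted_runs, -1)))
    last_idx = order[boundaries]
    run_at = sorted_runs[boundaries]
    keep = run_at > 0
    pidx = last_idx[keep]
    scores_flat = np.zeros_like(flat_kappa)
    scores_flat[pidx] = flat_kappa[pidx] * widths[run_at[keep] - 1]
    return scores_flat.reshape(n, L + 1)[:, :L]


def _connectivity_filter(plane: np.ndarray, axis: int) -> np.ndarray:
    """Reinforce responses flanked by responses along the scan direction:
    out = plane + min(max of 2 neighbours ahead, max of 2 behind)."""
    p = np.moveaxis(plane, axis, 1)
    padded = np.pad(p, ((0, 0), (2, 2)))
    ahead = np.maximum(padded[:, 3:-1], padded[:, 4:])
    behind = np.maximum(padded[:, 1:-3], padded[:, :-4])
    out = p + np.minimum(ahead, behind)
    return np.moveaxis(out, 1, axis)


def _diag_indices(shape: tuple[int, int], anti: bool):
    """Padded (rows, cols, valid) index arrays covering every diagonal."""
    h, w = shape
    maxlen = min(h, w)
    offsets = range(-(h - 1), w)
    n = len(offsets)
    rows = np.zeros((n, maxlen), dtype=int)
    cols = np.zeros((n, maxlen), dtype=int)
    valid = np.zeros((n, maxlen), dtype=bool)
    for i, k in enumerate(offsets):
        r0 = max(0, -k)
        length = min(h - r0, w - max(0, k))
        rr = np.arange(r0, r0 + length)
        cc = rr + k
        rows[i, :length] = rr
        cols[i, :length] = cc if not anti else (w - 1 - cc)
        valid[i, :length] = True
    return rows, cols, valid


def _direction_plane(
    img: np.ndarray, mask: np.ndarray, direction: str, params: MCParams
) -> np.ndarray:
    if direction == "transverse":
        scores = _score_profiles(img, mask, params.profile_sigma_px)
        if params.connectivity_filter:
            scores = _connectivity_filter(scores, axis=1)
        return scores
    if direction == "longitudinal":
        scores = _score_profiles(img.T, mask.T, params.profile_sigma_px)
        if params.connectivity_filter:
            scores = _connectivity_filter(scores, axis=1)
        return scores.T
    anti = direction == "antidiagonal"
    rows, cols, valid = _diag_indices(img.shape, anti)
    profiles = img[rows, cols]
    pvalid = mask[rows, cols] & valid
    scores = _score_profiles(profiles, pvalid, params.profile_sigma_px)
    if params.connectivity_filter:
        scores = _connectivity_filter(scores, axis=1)
    plane = np.zeros_like(img, dtype=float)
    plane[rows[valid], cols[valid]] = scores[valid]
    return plane


def curvature_scores(
    finger: FingerImage, params: MCParams | None = None
) -> np.ndarray:
    """Accumulated multi-direction curvature score plane (>= 0, zero
    outside the eroded finger mask)."""
    if params is None:
        params = MCParams()
    unknown = set(params.directions) - set(DIRECTIONS)
    if unknown:
        raise ValueError(f"unknown scan directions {sorted(unknown)}")
    mask = finger.mask.astype(bool)
    if not mask.any():
        raise ValueError("finger mask is empty")
    img = finger.image.astype(float)
    # gain/offset invariance: standardize within the mask
    mu, sd = img[mask].mean(), img[mask].std()
    if sd > 0:
        img = (img - mu) / sd
    else:
        img = img - mu
    inner = mask
    if params.mask_erosion_px > 0:
        inner = ndimage.binary_erosion(mask, iterations=params.mask_erosion_px)
    total = np.zeros_like(img)
    for direction in params.directions:
        total += np.maximum(_direction_plane(img, mask, direction, params), 0.0)
    total[~inner] = 0.0
    return total


def extract_mc(finger: FingerImage, params: MCParams | None = None) -> VeinTemplate:
    """Binary maximum-curvature template from a normalized finger image."""
    if params is None:
        params = MCParams()
    scores = curvature_scores(finger, params)
    positive = scores[scores > 0]
    if positive.size == 0:
        raise EmptyTemplateError("flat profile everywhere: no vein response")
    threshold = float(np.median(positive))
    # tiny relative tolerance so floating-point ties at the median land on
    # the active side together
    feature_map = scores >= threshold - 1e-9 * float(positive.max())
    return VeinTemplate(
        feature_map=feature_map,
        finger_label=finger.finger_label,
        provenance={
            "method": "maximum_curvature",
            "profile_sigma_px": params.profile_sigma_px,
            "directions": list(params.directions),
            "connectivity_filter": params.connectivity_filter,
            "binarization": "median_of_positive_scores",
        },
    )
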