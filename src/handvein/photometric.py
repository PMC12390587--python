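"""Photometric stereo: per-pixel surface normals and albedo from frames
captured under different known directional lights.

The Lambertian image formation model is I = L . N: stacking the per-source
intensities of one pixel into a vector I and the unit light directions
into the rows of L, the least-squares solution G = pinv(L) I recovers the
albedo-scaled normal; albedo = |G| and N = G/|G|.  Assumptions: distant
isotropic sources, Lambertian skin reflectance, smooth near-planar
surface.  Near-field illumination falloff is compensated beforehand by
flat-field division with a constant-albedo reference plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class SolvabilityError(ValueError):
    """Light-direction matrix is rank deficient."""


@dataclass
class LightRig:
    """Calibrated directional light sources with optional flat-field
    references (one constant-albedo reference image per source)."""

    directions: np.ndarray  # (n_lights, 3), unit rows
    flat_fields: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        L = np.asarray(self.directions, dtype=float)
        if L.ndim != 2 or L.shape[1] != 3 or L.shape[0] < 3:
            raise ValueError("need at least 3 light directions as (n, 3)")
        norms = np.linalg.norm(L, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("light directions must be unit-norm (within 1e-9)")
        self.directions = L
        if self.flat_fields is not None and len(self.flat_fields) != len(L):
            raise ValueError("need exactly one flat-field reference per source")

    def check_rank(self) -> None:
        s = np.linalg.svd(self.directions, compute_uv=False)
        if s[-1] < 1e-8 * s[0]:
            null = np.linalg.svd(self.directions)[2][-1]
            raise SolvabilityError(
                "light directions are rank deficient (coplanar): the normal "
                f"component along {np.round(null, 3)} is unobservable"
            )


@dataclass
class PhotometricResult:
    normal_map: np.ndarray  # (H, W, 3), unit vectors on valid pixels
    albedo_map: np.ndarray  # (H, W), >= 0
    residual_map: np.ndarray  # (H, W) per-pixel LSQ residual norm
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def flat_field_correct(
    frames: list[np.ndarray] | np.ndarray,
    rig: LightRig,
    eps: float = 1e-6,
) -> np.ndarray:
    """Divide each frame by its flat-field reference.

    The reference is an image of a constant-albedo plane under the same
    source, so the division cancels the inverse-square illumination
    falloff; output is scaled so a frame identical to its reference maps
    to 1.0 everywhere.  Pixels where the reference is (near) zero are set
    to NaN; if at least 1% of reference pixels are zero a warning is
    emitted.
    """
    if rig.flat_fields is None:
        raise ValueError("rig carries no flat-field references")
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) != len(rig.flat_fields):
        raise ValueError("one reference per frame required")
    out = []
    for frame, ref in zip(frames, rig.flat_fields):
        ref = np.asarray(ref, dtype=float)
        if ref.shape != frame.shape:
            raise ValueError("frame/reference dimension mismatch")
        dead = ref <= eps
        if dead.mean() >= 0.01:
            warnings.warn(
                f"{dead.mean():.1%} of flat-field pixels are zero; masking them",
                stacklevel=2,
            )
        corrected = frame / np.maximum(ref, eps)
        corrected[dead] = np.nan
        out.append(corrected)
    return np.stack(out)


def solve_normals(
    corrected: np.ndarray,
    rig: LightRig,
    shadow_quantile_frac: float = 0.02,
) -> PhotometricResult:
    """Least-squares normal/albedo recovery from a corrected frame stack.

    Per pixel, with L the (n, 3) light matrix and I the n observed
    intensities: G = pinv(L) I, albedo = |G|, normal = G/|G|.  Pixels in
    self or cast shadow are masked: any pixel whose intensity in some
    frame falls below ``shadow_quantile_frac`` times that frame's 99th
    percentile is flagged invalid, as are near-zero-albedo pixels.
    """
    stack = np.asarray(corrected, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != len(rig.directions):
        raise ValueError("corrected stack must be (n_lights, H, W)")
    rig.check_rank()
    n, h, w = stack.shape
    L = rig.directions
    pinv = np.linalg.pinv(L)

    I = stack.reshape(n, -1)
    finite = np.isfinite(I).all(axis=0)
    I_safe = np.where(np.isfinite(I), I, 0.0)
    G = pinv @ I_safe  # (3, H*W)
    albedo = np.linalg.norm(G, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = G / np.maximum(albedo, 1e-30)
    residual = np.linalg.norm(L @ G - I_safe, axis=0)

    floor = shadow_quantile_frac * np.nanpercentile(
        np.where(finite, I, np.nan).reshape(n, h, w), 99, axis=(1, 2)
    )
    lit = (I_safe >= floor[:, None]).all(axis=0)
    valid = finite & lit & (albedo > 1e-12)
    normals[:, ~valid] = 0.0

    return PhotometricResult(
        normal_map=normals.T.reshape(h, w, 3),
        albedo_map=albedo.reshape(h, w),
        residual_map=residual.reshape(h, w),
        valid_mask=valid.reshape(h, w),
    )


def integrate_normals(normal_map: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Optional utility: depth from normals by frequency-domain (Fourier)
    integration of the gradient field.  Returns relative depth (unknown
    constant offset); invalid pixels contribute zero gradient."""
    nz = np.where(valid_mask, normal_map[..., 2], 1.0)
    nz = np.where(np.abs(nz) < 1e-6, 1e-6, nz)
    p = np.where(valid_mask, -normal_map[..., 0] / nz, 0.0)
    q = np.where(valid_mask, -normal_map[..., 1] / nz, 0.0)
    h, w = p.shape
    wx = np.fft.fftfreq(w) * 2 * np.pi
    wy = np.fft.fftfreq(h) * 2 * np.pi
    u, v = np.meshgrid(wx, wy)
    denom = u**2 + v**2
    denom[0, 0] = 1.0
    Z = (-1j * u * np.fft.fft2(p) - 1j * v * np.fft.fft2(q)) / denom
    Z[0, 0] = 0.0
    depth = np.real(np.fft.ifft2(Z))
    # the mean (DC) gradient lies in the Fourier operator's null space;
    # restore it as an explicit ramp
    yy, xx = np.mgrid[0:h, 0:w]
    return depth + p[valid_mask].mean() * xx + q[valid_mask].mean() * yy
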