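"""Thin-lens optical model of the acquisition geometry.

Depth of field, hyperfocal distance, angles of view and first-order field
of view for a fixed-focal-length camera observing a hand at short range.
All distances are millimetres, angles degrees.

The standard thin-lens relations are used:

    H  = f^2 / (N c) + f                (hyperfocal distance)
    Dn = s (H - f) / (H + s - 2 f)      (near limit of acceptable sharpness)
    Df = s (H - f) / (H - s)            (far limit; infinite for s >= H)

with ``f`` the focal length, ``N`` the f-number, ``c`` the circle of
confusion and ``s`` the focussed distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CameraSpec:
    """Optical parameters of one camera module.

    The sensor is mounted in portrait orientation: the *short* physical
    side of the active area spans the image's horizontal axis.
    """

    focal_length_mm: float
    f_number: float
    circle_of_confusion_mm: float
    sensor_width_mm: float
    sensor_height_mm: float
    pixel_pitch_um: float = 3.4

    def __post_init__(self) -> None:
        for name in (
            "focal_length_mm",
            "f_number",
            "circle_of_confusion_mm",
            "sensor_width_mm",
            "sensor_height_mm",
            "pixel_pitch_um",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def sensor_diagonal_mm(self) -> float:
        return math.hypot(self.sensor_width_mm, self.sensor_height_mm)

    @property
    def focal_length_px(self) -> float:
        """Focal length expressed in pixel units (f / pixel pitch)."""
        return self.focal_length_mm / (self.pixel_pitch_um * 1e-3)


@dataclass(frozen=True)
class DofResult:
    """Depth-of-field bundle for one focus setting (all mm)."""

    hyperfocal_mm: float
    near_limit_mm: float
    far_limit_mm: float
    dof_mm: float
    focus_distance_mm: float
    far_limit_infinite: bool = False


def hyperfocal_distance(spec: CameraSpec) -> float:
    """Hyperfocal distance H = f^2/(N c) + f in millimetres."""
    f = spec.focal_length_mm
    return f * f / (spec.f_number * spec.circle_of_confusion_mm) + f


def depth_of_field(spec: CameraSpec, focus_distance_mm: float) -> DofResult:
    """Near/far sharpness limits and total depth of field at a focus distance.

    Parameters
    ----------
    spec:
        Camera optical parameters.
    focus_distance_mm:
        Focussed distance ``s``; must exceed the focal length.

    Returns
    -------
    DofResult
        When ``s >= H`` the far limit is infinite: ``far_limit_mm`` is
        ``math.inf``, ``far_limit_infinite`` is set and ``dof_mm`` is
        infinite as well (no exception is raised).
    """
    f = spec.focal_length_mm
    s = float(focus_distance_mm)
    if s <= f:
        raise ValueError(
            f"focus distance ({s} mm) must exceed the focal length ({f} mm)"
        )
    H = hyperfocal_distance(spec)
    near = s * (H - f) / (H + s - 2.0 * f)
    if s >= H:
        return DofResult(H, near, math.inf, math.inf, s, far_limit_infinite=True)
    far = s * (H - f) / (H - s)
    return DofResult(H, near, far, far - near, s)


def angles_of_view(spec: CameraSpec) -> tuple[float, float, float]:
    """(horizontal, vertical, diagonal) angles of view in degrees.

    ``angle = 2 atan(d / 2f)`` with ``d`` the sensor extent along the
    respective axis.  In portrait orientation the horizontal axis maps to
    the short physical side of the sensor.
    """
    f = spec.focal_length_mm
    short = min(spec.sensor_width_mm, spec.sensor_height_mm)
    long_ = max(spec.sensor_width_mm, spec.sensor_height_mm)

    def aov(d: float) -> float:
        return math.degrees(2.0 * math.atan(d / (2.0 * f)))

    return aov(short), aov(long_), aov(spec.sensor_diagonal_mm)


def field_of_view_at(
    spec: CameraSpec, distance_mm: float
) -> tuple[float, float, float]:
    """First-order (pinhole) field of view at a working distance, in mm.

    ``extent = distance * sensor_extent / f`` for the horizontal (short
    side, portrait), vertical (long side) and diagonal extents.
    """
    if not distance_mm > 0:
        raise ValueError("distance must be strictly positive")
    f = spec.focal_length_mm
    short = min(spec.sensor_width_mm, spec.sensor_height_mm)
    long_ = max(spec.sensor_width_mm, spec.sensor_height_mm)
    scale = distance_mm / f
    return short * scale, long_ * scale, spec.sensor_diagonal_mm * scale


def optics_report(spec: CameraSpec, focus_distance_mm: float) -> dict:
    """All optics quantities for one configuration, as a flat dict."""
    dof = depth_of_field(spec, focus_distance_mm)
    h, v, d = angles_of_view(spec)
    fh, fv, fd = field_of_view_at(spec, focus_distance_mm)
    return {
        "hyperfocal_mm": dof.hyperfocal_mm,
        "near_limit_mm": dof.near_limit_mm,
        "far_limit_mm": dof.far_limit_mm,
        "dof_mm": dof.dof_mm,
        "aov_horizontal_deg": h,
        "aov_vertical_deg": v,
        "aov_diagonal_deg": d,
        "fov_horizontal_mm": fh,
        "fov_vertical_mm": fv,
        "fov_diagonal_mm": fd,
    }
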