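"""Closed-form triangulation for a vertical stereo rig with rotated optical axes.

The rig consists of two identical cameras, C1 and C2, mounted on a vertical
baseline of length ``B``.  Both optical axes are parallel and tilted by a
common rotation angle ``alpha`` away from the perpendicular to the baseline;
``alpha = 0`` recovers classical stereovision.  Pixel coordinates along the
baseline-aligned image axis are signed, with the origin at the image center
and the positive direction chosen so that an object lying between the two
optical axes projects to ``y1 > 0`` in C1 and ``y2 < 0`` in C2, giving a
positive disparity ``y1 - y2``.

Distances ``D`` are measured from C1 to the *object plane*, the plane through
the object perpendicular to the optical axes.  The signed in-plane offset of
the object from C1's optical axis (positive toward C2) is called ``lateral``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "RigGeometry",
    "PixelObservation",
    "TriangulationIntermediates",
    "Localization",
    "ForwardProjection",
    "OutOfSensorError",
    "NonTriangulableError",
    "DegenerateRayError",
    "pixel_to_tangent",
    "tangent_to_pixel",
    "quantize_pixels",
    "forward_project",
    "triangulate_distance",
    "classical_distance",
    "altitude_eq10",
    "altitude_from_ray",
    "lateral_from_altitude",
]


class OutOfSensorError(ValueError):
    """A pixel coordinate lies outside the sensor (|y| > y0/2)."""


class NonTriangulableError(ValueError):
    """Disparity below one pixel: the object is at or behind stereo infinity."""


class DegenerateRayError(ValueError):
    """The altitude formula is evaluated at a degenerate ray angle."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Single-camera parameters.

    Parameters
    ----------
    y0 : int
        Vertical (disparity-axis) resolution in pixels; must be even so the
        center-origin pixel convention is well defined.
    phi0 : float
        Vertical field of view in degrees.
    f : float
        Focal length in mm.
    sia : float
        Sensor image dimension along the disparity axis in mm.
    """

    y0: int = 1440
    phi0: float = 48.8
    f: float = 3.0
    sia: float = 3.76

    def __post_init__(self) -> None:
        if self.y0 <= 0 or self.y0 % 2:
            raise ValueError(f"y0 must be positive and even, got {self.y0}")
        if not 0.0 < self.phi0 < 180.0:
            raise ValueError(f"phi0 must be in (0, 180) degrees, got {self.phi0}")
        if self.f <= 0 or self.sia <= 0:
            raise ValueError("focal length and sensor dimension must be positive")

    @property
    def half_res(self) -> float:
        """Half the vertical resolution, y0/2 (px)."""
        return self.y0 / 2.0

    @property
    def tan_half_fov(self) -> float:
        """tan(phi0/2)."""
        return math.tan(math.radians(self.phi0) / 2.0)

    @property
    def horizontal_fov(self) -> float:
        """Horizontal field of view (degrees) derived from sensor size and f."""
        return 2.0 * math.degrees(math.atan(self.sia / (2.0 * self.f)))


@dataclass(frozen=True)
class RigGeometry:
    """Stereo-pair geometry.

    Parameters
    ----------
    B : float
        Baseline length in m.
    alpha : float
        Rotation angle of both (parallel) optical axes, measured from the
        perpendicular to the baseline, in degrees.  ``alpha = 0`` is
        classical stereovision.
    mount_height : float
        Height of camera C1 above ground in m.
    """

    B: float = 1.0
    alpha: float = 24.4
    mount_height: float = 0.0

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError(f"baseline must be positive, got {self.B}")
        if not 0.0 <= self.alpha < 90.0:
            raise ValueError(f"alpha must be in [0, 90) degrees, got {self.alpha}")

    @property
    def alpha_rad(self) -> float:
        return math.radians(self.alpha)

    @property
    def cos_alpha(self) -> float:
        return math.cos(self.alpha_rad)

    @property
    def sin_alpha(self) -> float:
        return math.sin(self.alpha_rad)


@dataclass(frozen=True)
class PixelObservation:
    """Paired per-camera pixel measurements at one timestamp.

    ``y1``/``y2`` are signed center-origin pixel coordinates of the object
    center along the disparity axis (real-valued; detection may be subpixel).
    ``xc``/``yc`` are the horizontal and vertical centroid coordinates, and
    ``pW``/``pH`` the bounding-box width and height in pixels.
    """

    t: float
    y1: float
    y2: float
    xc: float = 0.0
    yc: float = 0.0
    pW: float = 0.0
    pH: float = 0.0

    def __post_init__(self) -> None:
        if self.pW < 0 or self.pH < 0:
            raise ValueError("bounding-box dimensions must be non-negative")

    @property
    def disparity(self) -> float:
        return self.y1 - self.y2


@dataclass(frozen=True)
class TriangulationIntermediates:
    """Auxiliary segment lengths of the triangulation geometry (all m).

    ``Db`` is the object-to-baseline-line length along the axis-parallel
    direction, ``Dk`` the object distance to the baseline line (equal to
    ``D`` in the axis-aligned frame), ``b0`` the signed position of the foot
    point along the baseline from C1, ``b1``/``b2`` the lateral offsets from
    the two optical axes to the object, and ``d1``/``d2`` the axial offsets
    of the cameras to the foot point.  They satisfy ``b1 + b2 = B cos(alpha)``
    and ``d1 + d2 = B sin(alpha)``.
    """

    Db: float
    Dk: float
    b0: float
    b1: float
    b2: float
    d1: float
    d2: float


@dataclass(frozen=True)
class Localization:
    """Triangulated distance and altitude for one observation.

    ``D`` is the distance from C1 to the object plane (m), ``H`` the object
    altitude above ground (m), ``dD`` the quantization uncertainty of ``D``
    (m, one discrete step of the distance function, ``D / (y1 - y2)``), and
    ``phi1``/``phi2`` the signed ray angles in the two cameras (degrees).
    """

    D: float
    H: float
    dD: float
    phi1: float
    phi2: float


class ForwardProjection(NamedTuple):
    """Result of projecting a metric position into both image planes."""

    y1: float
    y2: float
    in_fov: bool
    intermediates: TriangulationIntermediates


def pixel_to_tangent(y, intr: CameraIntrinsics):
    """Convert a signed center-origin pixel coordinate to a ray tangent.

    Returns ``tan(phi) = y * tan(phi0/2) / (y0/2)``; the sign of ``y`` is
    preserved.  Accepts scalars or arrays.
    """
    y = np.asarray(y, dtype=float)
    if np.any(np.abs(y) > intr.half_res):
        raise OutOfSensorError(f"|y| exceeds y0/2 = {intr.half_res}")
    out = y * intr.tan_half_fov / intr.half_res
    return float(out) if out.ndim == 0 else out


def tangent_to_pixel(tan_phi, intr: CameraIntrinsics):
    """Inverse of :func:`pixel_to_tangent` (may fall outside the sensor)."""
    tan_phi = np.asarray(tan_phi, dtype=float)
    out = tan_phi * intr.half_res / intr.tan_half_fov
    return float(out) if out.ndim == 0 else out


def quantize_pixels(y, intr: CameraIntrinsics | None = None):
    """Round to the nearest integer pixel, ties away from zero.

    With an intrinsics context the result is clipped to ``[-y0/2, y0/2]``.
    Accepts scalars or arrays; returns int or an int array.
    """
    y = np.asarray(y, dtype=float)
    q = np.copysign(np.floor(np.abs(y) + 0.5), y)
    if intr is not None:
        q = np.clip(q, -intr.half_res, intr.half_res)
    q = q.astype(int)
    return int(q) if q.ndim == 0 else q


def _distance_pixels(dy, y2, rig: RigGeometry, intr: CameraIntrinsics):
    """Distance from integer-pixel disparity and y2 (vectorized, no checks).

    ``D = B cos(a) y0 / (2 tan(phi0/2) (y1 - y2)) + B sin(a) y2 / (y1 - y2)``.
    """
    dy = np.asarray(dy, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    c = rig.B * rig.cos_alpha * intr.y0 / (2.0 * intr.tan_half_fov)
    return (c + rig.B * rig.sin_alpha * y2) / dy


def lateral_from_altitude(D, H, rig: RigGeometry):
    """Signed in-plane offset from C1's axis for an object at distance/altitude.

    Inverse of ``H = mount_height + D sin(alpha) - lateral cos(alpha)``;
    positive ``lateral`` points from C1's axis toward C2.
    """
    return (rig.mount_height + np.asarray(D, float) * rig.sin_alpha - np.asarray(H, float)) / rig.cos_alpha


def forward_project(
    D: float, lateral: float, rig: RigGeometry, intr: CameraIntrinsics
) -> ForwardProjection:
    """Project a metric position into real-valued pixel coordinates.

    Parameters
    ----------
    D : float
        Distance from C1 to the object plane (m), ``D > 0``.
    lateral : float
        Signed in-plane offset from C1's optical axis (m), positive toward C2.

    Returns the unquantized ``(y1, y2)``, an in-FoV flag (False when either
    projection falls outside ``[-y0/2, y0/2]``), and the triangulation
    intermediates.  Substituting the returned pixels into the pixel-space
    distance formula recovers ``D`` exactly.
    """
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    depth2 = D + rig.B * rig.sin_alpha
    if depth2 <= 0:
        raise ValueError("object lies behind camera C2")
    scale = intr.half_res / intr.tan_half_fov
    y1 = scale * lateral / D
    y2 = scale * (lateral - rig.B * rig.cos_alpha) / depth2
    in_fov = bool(abs(y1) <= intr.half_res and abs(y2) <= intr.half_res)
    tan_alpha = rig.sin_alpha / rig.cos_alpha
    inter = TriangulationIntermediates(
        Db=D + lateral * tan_alpha,
        Dk=D,
        b0=lateral / rig.cos_alpha,
        b1=lateral,
        b2=rig.B * rig.cos_alpha - lateral,
        d1=lateral * tan_alpha,
        d2=rig.B * rig.sin_alpha - lateral * tan_alpha,
    )
    return ForwardProjection(y1=float(y1), y2=float(y2), in_fov=in_fov, intermediates=inter)


def triangulate_distance(
    obs: PixelObservation, rig: RigGeometry, intr: CameraIntrinsics
) -> Localization:
    """Triangulate distance and altitude from a paired pixel observation.

    The distance is computed both directly in pixel space and via the ray
    angles; the two closed forms are algebraically identical and their
    agreement is asserted to machine tolerance as an internal consistency
    check.  The altitude is the geometry-consistent value obtained by
    intersecting the C1 ray with the object plane (see
    :func:`altitude_from_ray`); the quantization uncertainty is
    ``dD = D / (y1 - y2)``.
    """
    for y in (obs.y1, obs.y2):
        if abs(y) > intr.half_res:
            raise OutOfSensorError(f"|y| = {abs(y)} exceeds y0/2 = {intr.half_res}")
    dy = obs.disparity
    if dy < 1.0:
        raise NonTriangulableError(
            f"disparity {dy:.3f} px is below 1 px: object at or behind stereo infinity"
        )

    # pixel-space form
    d_pix = float(_distance_pixels(dy, obs.y2, rig, intr))
    # angle-space form
    tan1 = pixel_to_tangent(obs.y1, intr)
    tan2 = -pixel_to_tangent(obs.y2, intr)
    d_ang = rig.B * (rig.cos_alpha - rig.sin_alpha * tan2) / (tan1 + tan2)
    if not math.isclose(d_pix, d_ang, rel_tol=1e-9, abs_tol=1e-12):
        raise RuntimeError(
            f"internal inconsistency: pixel-form D={d_pix!r} vs angle-form D={d_ang!r}"
        )
    if d_pix <= 0:
        raise NonTriangulableError(f"non-physical distance {d_pix:.3f} m")

    phi1 = math.degrees(math.atan(tan1))
    phi2 = math.degrees(math.atan(tan2))
    lateral = d_pix * tan1
    h = rig.mount_height + d_pix * rig.sin_alpha - lateral * rig.cos_alpha
    return Localization(D=d_pix, H=h, dD=d_pix / dy, phi1=phi1, phi2=phi2)


def classical_distance(disparity: float, B: float, intr: CameraIntrinsics) -> float:
    """Classical (perpendicular-axes) stereo distance from disparity.

    ``D = B y0 / (2 tan(phi0/2) disparity)``; equals the rotated-axes formula
    at ``alpha = 0``.
    """
    if disparity < 1.0:
        raise NonTriangulableError(f"disparity {disparity} px is below 1 px")
    return B * intr.y0 / (2.0 * intr.tan_half_fov * disparity)


def altitude_eq10(D: float, phi2: float, intr: CameraIntrinsics) -> float:
    """Altitude from the literal closed form ``H = D cot(phi0/2 + phi2)``.

    This is the printed altitude formula of the source model; its angle
    convention cannot be reconciled unambiguously with the rig geometry, so
    the geometry-consistent :func:`altitude_from_ray` is provided alongside
    and used by the processing pipeline.
    """
    angle = intr.phi0 / 2.0 + phi2
    if not 0.0 < angle < 180.0 or math.isclose(angle % 180.0, 0.0, abs_tol=1e-12):
        raise DegenerateRayError(f"phi0/2 + phi2 = {angle} degrees is degenerate")
    return D / math.tan(math.radians(angle))


def altitude_from_ray(
    loc: Localization,
    obs: PixelObservation,
    rig: RigGeometry,
    intr: CameraIntrinsics,
) -> float:
    """Geometry-consistent altitude above ground.

    Intersects the C1 ray with the object plane at distance ``D`` and adds
    the axis elevation: ``H = mount_height + D sin(alpha) - lateral
    cos(alpha)`` with ``lateral = D tan(phi1)``.  Round-trips exactly with
    :func:`forward_project` in the absence of quantization.
    """
    lateral = loc.D * pixel_to_tangent(obs.y1, intr)
    return rig.mount_height + loc.D * rig.sin_alpha - lateral * rig.cos_alpha
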