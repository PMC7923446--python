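"""Metric size estimation and small/medium/large classification.

A detected animal's pixel bounding box (width ``pW``, height ``pH``) plus its
triangulated distance ``D`` give metric wingspan and height through the
pinhole relation ``PW = D pW SIA / (f y0)``.  The silhouette is approximated
by an isosceles triangle, whose area ``Oapprox = PW PH / 2`` serves as a
one-number size measure.  Class boundaries are the triangle areas of two
reference raptors: the common buzzard (wingspan 1.1 m, height 0.4 m, area
0.22 m^2) separates small from medium, the red kite (1.45 m, 0.66 m, area
0.4785 m^2, conventionally printed as 0.48) separates medium from large.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .stereo_geometry import CameraIntrinsics

__all__ = [
    "SizeClass",
    "SizeEstimate",
    "ClassBoundaries",
    "DEFAULT_BOUNDARIES",
    "size_from_pixels",
    "triangle_area",
    "boundaries_from_species",
    "classify",
]


class SizeClass(str, Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


@dataclass(frozen=True)
class SizeEstimate:
    """Metric size of one detection: wingspan, height (m), triangle area (m^2)
    and, when propagated, the wingspan uncertainty (m)."""

    PW: float
    PH: float
    Oapprox: float
    dPW: float | None = None


@dataclass(frozen=True)
class ClassBoundaries:
    """Small/medium (``ob1``) and medium/large (``ob2``) area boundaries, m^2."""

    ob1: float = 0.22
    ob2: float = 0.4785

    def __post_init__(self) -> None:
        if not 0 < self.ob1 < self.ob2:
            raise ValueError(f"boundaries must satisfy 0 < ob1 < ob2, got {self.ob1}, {self.ob2}")


def triangle_area(PW: float, PH: float) -> float:
    """Isosceles-triangle area ``PW * PH / 2`` (m^2)."""
    if PW < 0 or PH < 0:
        raise ValueError("dimensions must be non-negative")
    return PW * PH / 2.0


def boundaries_from_species(
    ref_small_to_medium: tuple[float, float] = (1.1, 0.4),
    ref_medium_to_large: tuple[float, float] = (1.45, 0.66),
    printed_rounding: bool = False,
) -> ClassBoundaries:
    """Derive class boundaries from (wingspan, height) of two boundary species.

    Defaults are the common buzzard and the red kite.  ``printed_rounding``
    rounds each boundary to two decimals (the conventional 0.22 / 0.48
    values) instead of keeping full precision.
    """
    dims = (*ref_small_to_medium, *ref_medium_to_large)
    if any(d <= 0 for d in dims):
        raise ValueError("species dimensions must be positive")
    ob1 = triangle_area(*ref_small_to_medium)
    ob2 = triangle_area(*ref_medium_to_large)
    if printed_rounding:
        ob1, ob2 = round(ob1, 2), round(ob2, 2)
    if ob1 >= ob2:
        raise ValueError(f"degenerate boundaries: ob1={ob1} >= ob2={ob2}")
    return ClassBoundaries(ob1=ob1, ob2=ob2)


DEFAULT_BOUNDARIES = boundaries_from_species()


def size_from_pixels(
    pW: float, pH: float, D: float, intr: CameraIntrinsics, dPW: float | None = None
) -> SizeEstimate:
    """Convert a pixel bounding box at distance ``D`` into a metric size."""
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    if pW < 0 or pH < 0:
        raise ValueError("pixel dimensions must be non-negative")
    scale = D * intr.sia / (intr.f * intr.y0)
    pw_m = pW * scale
    ph_m = pH * scale
    return SizeEstimate(PW=pw_m, PH=ph_m, Oapprox=triangle_area(pw_m, ph_m), dPW=dPW)


def classify(Oapprox: float, bounds: ClassBoundaries = DEFAULT_BOUNDARIES) -> SizeClass:
    """Map a triangle area to a size class.

    Intervals are ``[0, ob1)`` small, ``[ob1, ob2)`` medium, ``[ob2, inf)``
    large: an object exactly at a boundary belongs to the larger class.
    """
    if Oapprox < 0:
        raise ValueError("Oapprox must be non-negative")
    if Oapprox < bounds.ob1:
        return SizeClass.SMALL
    if Oapprox < bounds.ob2:
        return SizeClass.MEDIUM
    return SizeClass.LARGE
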