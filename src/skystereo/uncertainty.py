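"""Quantization-uncertainty model of the rotated-axes stereo rig.

Integer pixel coordinates quantize the distance function, so each observed
disparity corresponds to a band of true distances.  The exact differential of
the pixel-space distance formula gives the band half-width

    dD = [y0 cos(a) / (2 tan(phi0/2)) + y2 sin(a)] * B / (y1 - y2)^2

which is algebraically identical to ``D / (y1 - y2)``.  Because ``dD`` grows
with both distance and the object's position ``y2`` on the C2 image plane
(for ``a > 0``), baseline selection trades rig size against worst-case
uncertainty at the range limit; :func:`baseline_sweep` implements that trade
study.  The same differential approach propagates a one-pixel bounding-box
quantum into the metric wingspan estimate (:func:`size_measure_uncertainty`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stereo_geometry import (
    CameraIntrinsics,
    NonTriangulableError,
    PixelObservation,
    RigGeometry,
    _distance_pixels,
    triangulate_distance,
)

__all__ = [
    "UncertaintySurface",
    "BaselineSweepRow",
    "quantization_uncertainty",
    "uncertainty_surface",
    "baseline_sweep",
    "size_measure_uncertainty",
    "wingspan_band",
]


@dataclass(frozen=True)
class UncertaintySurface:
    """Distance and its quantization uncertainty on the integer pixel grid.

    All four arrays are 1-D, aligned element-wise (long format): each entry
    is one integer ``(disparity, y2)`` cell with ``0 < D <= max_range``.
    """

    disparities: np.ndarray
    y2_values: np.ndarray
    D_grid: np.ndarray
    dD_grid: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.disparities, self.y2_values, self.D_grid, self.dD_grid)}
        if len(shapes) != 1:
            raise ValueError("surface grids must share shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disparity": self.disparities,
                "y2": self.y2_values,
                "D": self.D_grid,
                "dD": self.dD_grid,
            }
        )


@dataclass(frozen=True)
class BaselineSweepRow:
    """Worst-case uncertainty at the range limit for one candidate baseline.

    ``min_disparity_*`` is the smallest integer disparity whose distance does
    not exceed the range limit, and ``worst_dD_*`` the uncertainty there, for
    the two center-origin extremes of ``y2`` (``low`` = -y0/2, ``high`` =
    +y0/2).  ``reachable`` is False when no integer disparity attains the
    range (flagged row).
    """

    B: float
    min_disparity_low: int
    worst_dD_low: float
    min_disparity_high: int
    worst_dD_high: float
    reachable: bool = True

    @property
    def worst_dD_at_range(self) -> float:
        return max(self.worst_dD_low, self.worst_dD_high)

    @property
    def min_disparity_at_range(self) -> int:
        return min(self.min_disparity_low, self.min_disparity_high)


def quantization_uncertainty(
    obs: PixelObservation, rig: RigGeometry, intr: CameraIntrinsics
) -> float:
    """Quantization uncertainty of the distance for one observation (m).

    Evaluates the exact-differential form and asserts its identity with
    ``D / (y1 - y2)`` to machine tolerance.
    """
    dy = obs.disparity
    if dy < 1.0:
        raise NonTriangulableError(f"disparity {dy:.3f} px is below 1 px")
    dd = (
        (intr.y0 * rig.cos_alpha / (2.0 * intr.tan_half_fov) + obs.y2 * rig.sin_alpha)
        * rig.B
        / dy**2
    )
    loc = triangulate_distance(obs, rig, intr)
    if not math.isclose(dd, loc.D / dy, rel_tol=1e-9, abs_tol=1e-12):
        raise RuntimeError("differential and ratio forms of dD disagree")
    return float(dd)


def uncertainty_surface(
    rig: RigGeometry, intr: CameraIntrinsics, max_range: float
) -> UncertaintySurface:
    """Evaluate D and dD on the integer ``(disparity, y2)`` grid.

    The grid covers integer disparities from 1 px upward and integer ``y2``
    values for which ``y1 = y2 + disparity`` stays on the sensor, retaining
    only cells with ``0 < D <= max_range``.
    """
    if max_range <= 0:
        raise ValueError("max_range must be positive")
    half = int(intr.half_res)
    dy = np.arange(1, intr.y0 + 1)
    y2 = np.arange(-half, half + 1)
    dy_g, y2_g = np.meshgrid(dy, y2, indexing="ij")
    valid = (y2_g + dy_g) <= half
    d = _distance_pixels(dy_g, y2_g, rig, intr)
    valid &= (d > 0) & (d <= max_range)
    return UncertaintySurface(
        disparities=dy_g[valid].astype(float),
        y2_values=y2_g[valid].astype(float),
        D_grid=d[valid],
        dD_grid=d[valid] / dy_g[valid],
    )


def baseline_sweep(
    candidates: list[float],
    range_limit: float,
    y2_extremes: tuple[float, float],
    rig_template: RigGeometry,
    intr: CameraIntrinsics,
) -> list[BaselineSweepRow]:
    """Worst-case dD at the range limit for each candidate baseline.

    For each baseline the formula is evaluated at the last integer disparity
    whose distance still reaches ``range_limit`` (the smallest disparity with
    ``D <= range_limit``), at both supplied ``y2`` extremes.  Supports the
    selection rule "smallest B whose worst-case statistic meets a target".
    Note: the extremes are evaluated as formula bounds without requiring
    ``y1 = y2 + disparity`` to sit on the sensor.
    """
    if not candidates or any(b <= 0 for b in candidates):
        raise ValueError("baseline candidates must be non-empty and positive")
    if range_limit <= 0:
        raise ValueError("range_limit must be positive")
    lo, hi = sorted(y2_extremes)
    rows = []
    for b in candidates:
        rig = RigGeometry(B=b, alpha=rig_template.alpha, mount_height=rig_template.mount_height)
        per_extreme = []
        reachable = True
        for y2 in (lo, hi):
            num = float(_distance_pixels(1.0, y2, rig, intr))  # D at 1 px disparity
            if num <= 0:
                reachable = False
                per_extreme.append((0, math.nan))
                continue
            dy_min = max(1, math.ceil(num / range_limit))
            per_extreme.append((dy_min, num / dy_min**2))
        rows.append(
            BaselineSweepRow(
                B=b,
                min_disparity_low=per_extreme[0][0],
                worst_dD_low=per_extreme[0][1],
                min_disparity_high=per_extreme[1][0],
                worst_dD_high=per_extreme[1][1],
                reachable=reachable,
            )
        )
    return rows


def sweep_to_frame(rows: list[BaselineSweepRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "B": [r.B for r in rows],
            "min_disparity": [r.min_disparity_at_range for r in rows],
            "worst_dD_low": [r.worst_dD_low for r in rows],
            "worst_dD_high": [r.worst_dD_high for r in rows],
        }
    )


def size_measure_uncertainty(
    D: float, dD: float, pW: float, intr: CameraIntrinsics, d_pix: float = 1.0
) -> float:
    """Uncertainty of the metric wingspan estimate (m).

    Exact differential of ``PW = D pW SIA / (f y0)`` with a ``d_pix``-pixel
    bounding-box quantum: ``dPW = (SIA / (f y0)) (pW dD + D d_pix)``.
    """
    if D <= 0:
        raise ValueError("D must be positive")
    return intr.sia / (intr.f * intr.y0) * (pW * dD + D * d_pix)


def wingspan_band(
    wingspan: float, D, rig: RigGeometry, intr: CameraIntrinsics
):
    """Lower/upper wingspan-estimate envelope for a target class at distance D.

    Uses the continuous (unquantized) disparity of an on-axis object
    (``y2 = 0`` convention) to evaluate ``dD`` and the one-pixel width
    quantum; reproduces the class-separation bands of the size-uncertainty
    analysis.  Returns ``(low, high)`` arrays.
    """
    D = np.asarray(D, dtype=float)
    scale = intr.f * intr.y0 / intr.sia  # px*m per m of extent
    p_w = wingspan * scale / D
    dy = rig.B * rig.cos_alpha * intr.y0 / (2.0 * intr.tan_half_fov) / D
    d_d = D / dy
    d_pw = intr.sia / (intr.f * intr.y0) * (p_w * d_d + D)
    return wingspan - d_pw, wingspan + d_pw
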