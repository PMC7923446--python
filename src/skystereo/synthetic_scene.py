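"""Synthetic flight scenes: trajectories, stereo rendering, GPS-like tracks.

Emulates the validation campaign of the monitoring rig: bird-sized targets
fly past the station at near-constant distance and altitude while both
cameras record them.  Targets are rendered as filled isosceles triangles
(the same silhouette model the size classifier assumes), scaled by the
pinhole relation ``pW = wingspan * f * y0 / (D * SIA)`` and placed at the
forward-projected, integer-quantized pixel position, so the whole
detect/pair/triangulate/classify chain is testable without any field data.

The nine scenario presets reproduce the field test plan: three flights per
target size at the mean distances/altitudes, spreads and sample counts of
the campaign, with per-drone speeds of 4.0 / 20.0 / 15.0 m/s (small fixed
wing, medium fixed wing, large quadrocopter-class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .motion_detection import Frame
from .stereo_geometry import (
    CameraIntrinsics,
    RigGeometry,
    forward_project,
    lateral_from_altitude,
    quantize_pixels,
)

__all__ = [
    "TargetSpec",
    "Trajectory",
    "ReferenceTrack",
    "ScenarioPreset",
    "SCENARIO_PRESETS",
    "generate_trajectory",
    "scenario_presets",
    "render_stereo_frames",
    "make_background",
    "gps_like_reference",
    "triangle_mask",
]

DEFAULT_FPS = 15.0
DEFAULT_FRAME_WIDTH = 320
DEFAULT_GPS_NOISE_SD = (1.0, 0.5)


@dataclass(frozen=True)
class TargetSpec:
    """Physical target dimensions (m) and its nominal size label."""

    wingspan: float
    height: float
    label: str

    def __post_init__(self) -> None:
        if self.wingspan <= 0 or self.height <= 0:
            raise ValueError("target dimensions must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Time series of true target positions.

    ``D`` is the distance to the object plane, ``H`` the altitude, and
    ``lateral`` the horizontal (cross-plane) offset mapping to the image
    column; all in m.
    """

    t: np.ndarray
    D: np.ndarray
    H: np.ndarray
    lateral: np.ndarray
    speed: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.D <= 0):
            raise ValueError("distances must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ReferenceTrack:
    """GPS-like reference: the trajectory timestamps with noisy (D, H)."""

    t: np.ndarray
    D: np.ndarray
    H: np.ndarray
    noise_sd: tuple[float, float]
    seed: int


# Field test plan: (mean D [m], sd D [m], mean H [m], sd H [m], samples, size)
_SCENARIO_TABLE = {
    "I_S": (46.4, 0.3, 26.7, 0.2, 85, "small"),
    "II_S": (66.6, 2.2, 32.0, 0.2, 86, "small"),
    "III_S": (96.3, 10.8, 26.7, 0.1, 82, "small"),
    "IV_M": (104.2, 12.5, 36.1, 0.5, 99, "medium"),
    "V_M": (133.6, 13.7, 38.5, 2.3, 157, "medium"),
    "VI_M": (202.8, 1.6, 48.8, 1.7, 97, "medium"),
    "VII_L": (129.3, 2.5, 53.0, 0.7, 137, "large"),
    "VIII_L": (202.9, 4.9, 96.9, 0.7, 101, "large"),
    "IX_L": (311.5, 2.9, 102.9, 0.7, 31, "large"),
}

# Data-sheet dimensions of the three test drones (wingspan, height in m).
_TARGETS = {
    "small": TargetSpec(wingspan=0.24, height=0.10, label="small"),
    "medium": TargetSpec(wingspan=1.20, height=0.53, label="medium"),
    "large": TargetSpec(wingspan=1.99, height=1.04, label="large"),
}

# Mean speed per drone during the campaign (m/s).
_SPEEDS = {"small": 4.0, "medium": 20.0, "large": 15.0}


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    target: TargetSpec
    mean_D: float
    sd_D: float
    mean_H: float
    sd_H: float
    n_samples: int
    speed: float


SCENARIO_PRESETS: dict[str, ScenarioPreset] = {
    name: ScenarioPreset(
        name=name,
        target=_TARGETS[size],
        mean_D=d,
        sd_D=sd_d,
        mean_H=h,
        sd_H=sd_h,
        n_samples=n,
        speed=_SPEEDS[size],
    )
    for name, (d, sd_d, h, sd_h, n, size) in _SCENARIO_TABLE.items()
}


def generate_trajectory(
    mean_D: float,
    mean_H: float,
    speed: float,
    duration: float,
    jitter_sd: tuple[float, float] = (0.0, 0.0),
    fps: float = DEFAULT_FPS,
    seed: int = 0,
    smooth_frames: float = 5.0,
) -> Trajectory:
    """Simulate a pass at near-constant distance and altitude.

    Samples are spaced ``1/fps`` apart (``floor(duration*fps) + 1`` of them).
    ``D`` and ``H`` are the mean values plus temporally smoothed Gaussian
    jitter rescaled to the stated standard deviations; the horizontal
    coordinate is a constant-speed straight pass through the image center.
    Deterministic given ``seed``.
    """
    if mean_D <= 0 or fps <= 0 or duration < 0 or speed < 0 or mean_H < 0:
        raise ValueError("trajectory parameters must be non-negative (mean_D, fps positive)")
    n = int(math.floor(duration * fps)) + 1
    t = np.arange(n) / fps
    rng = np.random.default_rng(seed)

    def channel(sd: float) -> np.ndarray:
        if sd <= 0 or n < 2:
            return np.zeros(n)
        raw = gaussian_filter1d(rng.standard_normal(n), smooth_frames, mode="nearest")
        raw -= raw.mean()  # realized mean/sd pinned to the requested values
        std = raw.std()
        return raw * (sd / std) if std > 0 else np.zeros(n)

    d = mean_D + channel(jitter_sd[0])
    h = mean_H + channel(jitter_sd[1])
    lateral = speed * (t - t[-1] / 2.0)
    return Trajectory(t=t, D=d, H=h, lateral=lateral, speed=speed)


def scenario_presets(
    fps: float = DEFAULT_FPS, seed: int = 0
) -> dict[str, tuple[TargetSpec, Trajectory]]:
    """Build the nine named scenarios as (target, trajectory) pairs.

    Durations are chosen so that the sample count at ``fps`` matches each
    scenario's registered sample count; per-scenario seeds derive
    deterministically from ``seed``.
    """
    out = {}
    for idx, (name, preset) in enumerate(SCENARIO_PRESETS.items()):
        duration = (preset.n_samples - 1) / fps
        traj = generate_trajectory(
            mean_D=preset.mean_D,
            mean_H=preset.mean_H,
            speed=preset.speed,
            duration=duration,
            jitter_sd=(preset.sd_D, preset.sd_H),
            fps=fps,
            seed=seed * 1009 + idx,
        )
        out[name] = (preset.target, traj)
    return out


def triangle_mask(pW: int, pH: int) -> np.ndarray:
    """Boolean silhouette of a filled isosceles triangle, apex up.

    The bottom row spans the full width ``pW`` and every row is non-empty,
    so the tight bounding box of the mask is exactly ``pH`` x ``pW``.
    """
    if pW < 1 or pH < 1:
        raise ValueError("mask dimensions must be at least 1 px")
    mask = np.zeros((pH, pW), dtype=bool)
    for r in range(pH):
        w = max(1, int(math.ceil(pW * (r + 1) / pH)))
        left = (pW - w) // 2
        mask[r, left : left + w] = True
    return mask


def _paste(canvas: np.ndarray, mask: np.ndarray, row_c: int, col_c: int) -> None:
    """Paste a silhouette centered at (row_c, col_c); clips at the borders."""
    p_h, p_w = mask.shape
    top = row_c - (p_h - 1) // 2
    left = col_c - (p_w - 1) // 2
    r0, r1 = max(top, 0), min(top + p_h, canvas.shape[0])
    c0, c1 = max(left, 0), min(left + p_w, canvas.shape[1])
    if r0 >= r1 or c0 >= c1:
        return
    sub = mask[r0 - top : r1 - top, c0 - left : c1 - left]
    canvas[r0:r1, c0:c1][sub] = 255


def _pixel_extent(extent_m: float, depth: float, intr: CameraIntrinsics) -> int:
    """Rendered pixel size of a metric extent at axial depth (inverse of the
    size-estimation relation), rounded half away from zero."""
    return quantize_pixels(extent_m * intr.f * intr.y0 / (depth * intr.sia))


def render_stereo_frames(
    traj: Trajectory,
    target: TargetSpec,
    rig: RigGeometry,
    intr: CameraIntrinsics,
    background_noise_sd: float = 0.0,
    seed: int = 0,
    frame_width: int = DEFAULT_FRAME_WIDTH,
) -> tuple[list[Frame], list[Frame]]:
    """Render the trajectory into both cameras.

    At each sample the target triangle is drawn at the forward-projected,
    integer-quantized vertical pixel position of each camera; its pixel size
    follows the pinhole scale at that camera's axial depth.  The horizontal
    position maps the trajectory's cross-plane offset through the horizontal
    FoV (derived from sensor size and focal length) onto ``frame_width``
    columns.  Out-of-FoV samples, and targets whose extent rounds below one
    pixel, render empty frames.  Gaussian background noise (clipped 8-bit)
    is added with the given seed.
    """
    if not (
        np.all(np.isfinite(traj.D)) and np.all(np.isfinite(traj.H)) and np.all(np.isfinite(traj.lateral))
    ):
        raise ValueError("trajectory contains non-finite samples")
    rng = np.random.default_rng(seed)
    shape = (intr.y0, frame_width)
    tan_half_x = math.tan(math.radians(intr.horizontal_fov) / 2.0)
    frames1, frames2 = [], []
    for k in range(len(traj)):
        d, h, lat_h, t = traj.D[k], traj.H[k], traj.lateral[k], traj.t[k]
        lateral = float(lateral_from_altitude(d, h, rig))
        fp = forward_project(d, lateral, rig, intr)
        depths = (d, d + rig.B * rig.sin_alpha)
        for cam, y_real, depth, frames in (
            ("C1", fp.y1, depths[0], frames1),
            ("C2", fp.y2, depths[1], frames2),
        ):
            if background_noise_sd > 0:
                canvas = np.clip(
                    rng.normal(0.0, background_noise_sd, shape), 0, 255
                ).astype(np.uint8)
            else:
                canvas = np.zeros(shape, dtype=np.uint8)
            y_q = quantize_pixels(y_real)
            row_c = int(intr.half_res) - y_q
            col_c = int(
                round(frame_width / 2.0 + (frame_width / 2.0) * (lat_h / depth) / tan_half_x)
            )
            p_w = _pixel_extent(target.wingspan, depth, intr)
            p_h = _pixel_extent(target.height, depth, intr)
            if abs(y_q) <= intr.half_res and 0 <= row_c < intr.y0 and p_w >= 1 and p_h >= 1:
                _paste(canvas, triangle_mask(p_w, p_h), row_c, col_c)
            frames.append(Frame(t=float(t), pixels=canvas, camera_id=cam))
    return frames1, frames2


def make_background(
    intr: CameraIntrinsics,
    frame_width: int = DEFAULT_FRAME_WIDTH,
    t: float = -1.0 / DEFAULT_FPS,
    camera_id: str = "C1",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Frame:
    """An empty (target-free) frame usable as a static-scene reference."""
    shape = (intr.y0, frame_width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pixels = np.clip(rng.normal(0.0, noise_sd, shape), 0, 255).astype(np.uint8)
    else:
        pixels = np.zeros(shape, dtype=np.uint8)
    return Frame(t=t, pixels=pixels, camera_id=camera_id)


def gps_like_reference(
    traj: Trajectory,
    noise_sd: tuple[float, float] = DEFAULT_GPS_NOISE_SD,
    seed: int = 0,
) -> ReferenceTrack:
    """Reference track: the trajectory plus i.i.d. Gaussian recorder noise."""
    if noise_sd[0] < 0 or noise_sd[1] < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    d = traj.D + (rng.normal(0.0, noise_sd[0], len(traj)) if noise_sd[0] > 0 else 0.0)
    h = traj.H + (rng.normal(0.0, noise_sd[1], len(traj)) if noise_sd[1] > 0 else 0.0)
    return ReferenceTrack(t=traj.t.copy(), D=np.asarray(d), H=np.asarray(h), noise_sd=tuple(noise_sd), seed=seed)
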