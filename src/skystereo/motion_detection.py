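"""Motion-based blob extraction and stereo pairing.

Detection is two-frame absolute differencing followed by a fixed binary
threshold and 8-connected component labeling; components above a minimum
area become :class:`Blob` records with tight bounding boxes and
intensity-weighted centroids.  :func:`pair_stereo` matches blobs across the
two cameras of a rig by horizontal proximity and converts image rows to the
signed center-origin pixel coordinates used by the geometry module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .stereo_geometry import CameraIntrinsics, PixelObservation

__all__ = ["Frame", "Blob", "detect_moving", "pair_stereo", "row_to_signed_y"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 20
DEFAULT_MIN_AREA = 16


@dataclass(frozen=True)
class Frame:
    """One grayscale frame: timestamp (s), 8-bit pixel grid, camera id."""

    t: float
    pixels: np.ndarray
    camera_id: str = "C1"

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")
        if self.pixels.dtype != np.uint8:
            object.__setattr__(self, "pixels", self.pixels.astype(np.uint8))


@dataclass(frozen=True)
class Blob:
    """A connected moving region in one camera.

    ``xc, yc`` is the intensity-weighted centroid (px, image coordinates with
    row 0 at the top); ``bbox`` is the tight bounding box as
    ``(min_row, min_col, max_row, max_col)`` with exclusive maxima; ``pW``
    and ``pH`` are the box width and height, ``area`` the pixel count.
    """

    xc: float
    yc: float
    bbox: tuple[int, int, int, int]
    pW: int
    pH: int
    area: int
    camera_id: str = "C1"

    @property
    def yc_box(self) -> float:
        """Row coordinate of the bounding-box center (px)."""
        return (self.bbox[0] + self.bbox[2] - 1) / 2.0

    @property
    def xc_box(self) -> float:
        return (self.bbox[1] + self.bbox[3] - 1) / 2.0


def row_to_signed_y(row, intr: CameraIntrinsics):
    """Convert an image row index (0 at top) to signed center-origin y (px)."""
    return intr.half_res - np.asarray(row, dtype=float)


def detect_moving(
    frame_prev: Frame,
    frame_curr: Frame,
    threshold: float = DEFAULT_THRESHOLD,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[Blob]:
    """Extract moving blobs from a consecutive frame pair of one camera.

    Absolute frame difference -> binary threshold (``diff > threshold``) ->
    8-connected components -> components with ``area >= min_area`` returned
    with tight bounding boxes and intensity-weighted centroids.
    """
    if frame_prev.camera_id != frame_curr.camera_id:
        raise ValueError("frames must come from the same camera")
    if frame_prev.pixels.shape != frame_curr.pixels.shape:
        raise ValueError("frame shapes differ")
    if not frame_curr.t > frame_prev.t:
        raise ValueError("timestamps must be strictly increasing")

    diff = np.abs(frame_curr.pixels.astype(np.int16) - frame_prev.pixels.astype(np.int16))
    mask = diff > threshold
    labels = label(mask, connectivity=2)
    blobs = []
    for prop in regionprops(labels, intensity_image=diff.astype(float)):
        if prop.area < min_area:
            continue
        row_c, col_c = prop.centroid_weighted
        min_row, min_col, max_row, max_col = prop.bbox
        blobs.append(
            Blob(
                xc=float(col_c),
                yc=float(row_c),
                bbox=(int(min_row), int(min_col), int(max_row), int(max_col)),
                pW=int(max_col - min_col),
                pH=int(max_row - min_row),
                area=int(prop.area),
                camera_id=frame_curr.camera_id,
            )
        )
    return blobs


def pair_stereo(
    blobs1: list[Blob],
    blobs2: list[Blob],
    intr: CameraIntrinsics,
    max_x_offset: float = 30.0,
    t: float = 0.0,
) -> list[PixelObservation]:
    """Greedy one-to-one stereo correspondence between per-camera blob lists.

    Candidate pairs must satisfy ``|xc1 - xc2| <= max_x_offset`` and a
    disparity of at least 1 px after converting rows to signed center-origin
    coordinates; surviving pairs are matched greedily by increasing
    horizontal offset.  The vertical coordinate of each blob is its
    bounding-box center row, the estimator of the projected object center
    under the triangle silhouette model.  Unmatched blobs are dropped with a
    logged count.
    """
    candidates = []
    for i, b1 in enumerate(blobs1):
        for j, b2 in enumerate(blobs2):
            dx = abs(b1.xc_box - b2.xc_box)
            if dx > max_x_offset:
                continue
            y1 = float(row_to_signed_y(b1.yc_box, intr))
            y2 = float(row_to_signed_y(b2.yc_box, intr))
            if y1 - y2 < 1.0:
                continue
            candidates.append((dx, i, j, y1, y2))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used1: set[int] = set()
    used2: set[int] = set()
    observations = []
    for dx, i, j, y1, y2 in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        b1 = blobs1[i]
        observations.append(
            PixelObservation(
                t=t, y1=y1, y2=y2, xc=b1.xc_box, yc=b1.yc_box, pW=b1.pW, pH=b1.pH
            )
        )
    dropped = (len(blobs1) - len(used1)) + (len(blobs2) - len(used2))
    if dropped:
        logger.debug("pair_stereo dropped %d unmatched blob(s) at t=%s", dropped, t)
    return observations
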