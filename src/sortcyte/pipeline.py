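"""Acquisition-side real-time image analysis.

Mirrors the processing each camera frame undergoes before a sort decision:

1. a running-average background over the last 100 frames,
2. background subtraction and thresholding into a binary mask,
3. erosion + dilation (3x3 element) to despeckle,
4. external-contour extraction and counting,
5. morphometrics per contour — area (um^2), bounding box, orientation
   ("tilt") from second moments of area,
6. bounding-box-centred square crops (18 or 36 px) for the classifier.

Coordinate convention: row 0 at the top, x = flow axis = image columns,
0-based pixel indices.  Moments are computed about the contour centroid, so
tilt is translation-invariant; the orientation is

    phi = 1/2 * arctan(2 I_xy / -(I_yy - I_xx))

with I_xx = integral(y^2 dA), I_yy = integral(x^2 dA), I_xy = -integral(xy dA),
resolved to [-90, 90] deg by the two-argument arctangent; the reported tilt
is |phi|.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "BackgroundModel",
    "ContourMoments",
    "EventFeatures",
    "update_background",
    "segment",
    "find_contours",
    "contour_area_um2",
    "contour_moments",
    "tilt",
    "crop_centered",
    "analyze_frame",
]

#: Default threshold: ~2 sigma above the static-noise sd of 2.9 grayscale.
DEFAULT_THRESHOLD = 6.0


class BackgroundModel:
    """Running average of the last ``window`` frames (default 100).

    Backed by a ring buffer; until the buffer fills, the average runs over
    the frames seen so far.  Frames older than the window have no influence.
    """

    def __init__(self, window: int = 100):
        if window < 1:
            raise ValueError("window must be >= 1")
        self.window = window
        self._buffer: np.ndarray | None = None
        self._sum: np.ndarray | None = None
        self._idx = 0
        self._count = 0

    @property
    def n_seen(self) -> int:
        return self._count

    @property
    def current_background(self) -> np.ndarray:
        """Mean of the stored frames, float; raises before the first frame."""
        if self._sum is None or self._count == 0:
            raise ValueError("no frames seen yet")
        return self._sum / min(self._count, self.window)

    def update(self, frame: np.ndarray) -> "BackgroundModel":
        frame = np.asarray(frame, dtype=np.float64)
        if self._buffer is None:
            self._buffer = np.zeros((self.window, *frame.shape))
            self._sum = np.zeros(frame.shape)
        if frame.shape != self._buffer.shape[1:]:
            raise ValueError(
                f"frame shape {frame.shape} != model shape {self._buffer.shape[1:]}")
        if self._count >= self.window:
            self._sum -= self._buffer[self._idx]
        self._buffer[self._idx] = frame
        self._sum += frame
        self._idx = (self._idx + 1) % self.window
        self._count += 1
        return self


def update_background(model: BackgroundModel, frame: np.ndarray) -> BackgroundModel:
    """Feed one frame into the running-average background model."""
    return model.update(frame)


def segment(frame: np.ndarray, background: np.ndarray,
            threshold: float = DEFAULT_THRESHOLD,
            n_erode: int = 1, n_dilate: int = 1) -> np.ndarray:
    """Binary mask: |frame - background| > threshold, then erode/dilate.

    The absolute difference is thresholded (cells show both a dark rim and a
    bright interior), then ``n_erode`` erosions and ``n_dilate`` dilations
    with a full 3x3 structuring element despeckle the mask.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    mask = np.abs(frame - background) > threshold
    selem = np.ones((3, 3), dtype=bool)
    if n_erode:
        mask = ndimage.binary_erosion(mask, selem, iterations=n_erode)
    if n_dilate:
        mask = ndimage.binary_dilation(mask, selem, iterations=n_dilate)
    return mask


def find_contours(mask: np.ndarray) -> list[np.ndarray]:
    """External boundaries of connected components, largest area first.

    Holes inside a component are ignored (the mask is filled before contour
    tracing).  Each contour is an (N, 2) float array of (row, col) vertices
    forming a closed polygon at sub-pixel positions; an empty mask yields an
    empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    filled = ndimage.binary_fill_holes(mask)
    padded = np.pad(filled.astype(float), 1)
    contours = [c - 1.0 for c in measure.find_contours(padded, 0.5)]
    contours.sort(key=_polygon_area_px, reverse=True)
    return contours


def _polygon_area_px(contour: np.ndarray) -> float:
    """Unsigned shoelace area of a closed (row, col) polygon, px^2."""
    y = contour[:, 0]
    x = contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def contour_area_um2(contour: np.ndarray, pixel_size: float) -> float:
    """Enclosed area of a closed contour in um^2 (winding-independent)."""
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        warnings.warn("degenerate polygon (< 3 vertices); area 0", stacklevel=2)
        return 0.0
    return _polygon_area_px(contour) * pixel_size ** 2


@dataclass(frozen=True)
class ContourMoments:
    """Central second moments of area and the derived orientation.

    I_xx = integral(y^2 dA), I_yy = integral(x^2 dA), I_xy = -integral(xy dA),
    all about the centroid; phi in [-90, 90] degrees from the flow axis.
    ``degenerate`` marks (near-)isotropic contours whose orientation is
    undefined (circles); phi is reported as 0 there.
    """

    i_xx: float
    i_yy: float
    i_xy: float
    phi_deg: float
    degenerate: bool


def contour_moments(contour: np.ndarray, rel_tol: float = 1e-3) -> ContourMoments:
    """Exact polygon second moments (Green's theorem) about the centroid."""
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[0] < 3:
        raise ValueError("need a closed polygon with >= 3 vertices")
    # x along columns (flow axis), y along rows
    x = c[:, 1]
    y = c[:, 0]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area < 0:  # normalise winding so the integrals carry the right sign
        x, y, x1, y1 = x[::-1], y[::-1], np.roll(x[::-1], -1), np.roll(y[::-1], -1)
        cross = x * y1 - x1 * y
        area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("zero-area polygon")
    cx = np.sum((x + x1) * cross) / (6.0 * area)
    cy = np.sum((y + y1) * cross) / (6.0 * area)
    mxx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0     # int x^2 dA
    myy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0     # int y^2 dA
    mxy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    # central moments
    mu20 = mxx - area * cx * cx   # int (x-cx)^2 dA
    mu02 = myy - area * cy * cy   # int (y-cy)^2 dA
    mu11 = mxy - area * cx * cy   # int (x-cx)(y-cy) dA
    aniso = math.hypot(mu20 - mu02, 2.0 * mu11)
    degenerate = aniso <= rel_tol * (mu20 + mu02)
    if degenerate:
        phi = 0.0
    else:
        phi = 0.5 * math.degrees(math.atan2(2.0 * mu11, mu20 - mu02))
    return ContourMoments(i_xx=myy, i_yy=mxx, i_xy=-mxy,
                          phi_deg=phi, degenerate=degenerate)


def tilt(contour: np.ndarray) -> float:
    """Absolute contour orientation vs the flow axis, degrees in [0, 90].

    Circularly symmetric contours (degenerate moments) report 0; use
    :func:`contour_moments` when the degeneracy flag is needed.
    """
    return abs(contour_moments(contour).phi_deg)


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def crop_centered(frame: np.ndarray, bbox_middle: tuple[float, float],
                  size: int, background: np.ndarray | None = None) -> np.ndarray:
    """size x size crop centred at round(bbox_middle), padded where needed.

    ``bbox_middle`` is (row, col); rounding is half-away-from-zero so crops
    are bit-reproducible.  Out-of-frame regions are padded with the local
    median of the background model (or of the frame itself when no
    background is supplied).
    """
    if size <= 0 or size % 2:
        raise ValueError("size must be even and positive")
    frame = np.asarray(frame)
    r0 = _round_half_away(bbox_middle[0]) - size // 2
    c0 = _round_half_away(bbox_middle[1]) - size // 2
    ref = frame if background is None else np.asarray(background)
    rs = slice(max(r0, 0), min(r0 + size, frame.shape[0]))
    cs = slice(max(c0, 0), min(c0 + size, frame.shape[1]))
    pad_region = ref[rs, cs]
    pad_value = np.median(pad_region) if pad_region.size else np.median(ref)
    out = np.full((size, size), pad_value, dtype=frame.dtype)
    out[rs.start - r0:rs.stop - r0, cs.start - c0:cs.stop - c0] = frame[rs, cs]
    return out


@dataclass(frozen=True)
class EventFeatures:
    """Contour-derived features of one event (largest contour in frame)."""

    n_contours: int
    area_um2: float
    bbox: tuple[int, int, int, int]        # (row0, col0, row1, col1), half-open
    bbox_middle: tuple[float, float]       # (row, col)
    tilt_deg: float
    crop18: np.ndarray
    crop36: np.ndarray
    timestamp: float = 0.0
    fluorescence: float = float("nan")


def analyze_frame(frame: np.ndarray, background: np.ndarray,
                  pixel_size: float, threshold: float = DEFAULT_THRESHOLD,
                  n_erode: int = 1, n_dilate: int = 1,
                  timestamp: float = 0.0,
                  fluorescence: float = float("nan")) -> EventFeatures | None:
    """Full per-frame chain: segment -> contours -> morphometrics -> crops.

    Returns None when no contour is found.  Features describe the largest
    contour; ``n_contours`` counts all of them (the aggregate gate needs it).
    """
    mask = segment(frame, background, threshold, n_erode, n_dilate)
    contours = find_contours(mask)
    if not contours:
        return None
    main = contours[0]
    r_min, c_min = main.min(axis=0)
    r_max, c_max = main.max(axis=0)
    bbox = (int(math.floor(r_min)), int(math.floor(c_min)),
            int(math.ceil(r_max)) + 1, int(math.ceil(c_max)) + 1)
    middle = ((r_min + r_max) / 2.0, (c_min + c_max) / 2.0)
    return EventFeatures(
        n_contours=len(contours),
        area_um2=contour_area_um2(main, pixel_size),
        bbox=bbox,
        bbox_middle=middle,
        tilt_deg=tilt(main),
        crop18=crop_centered(frame, middle, 18, background),
        crop36=crop_centered(frame, middle, 36, background),
        timestamp=timestamp,
        fluorescence=fluorescence,
    )
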