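"""Ground-truthed synthetic imaging-flow-cytometry streams.

Emulates what the high-speed camera of a sorting deformability cytometer
sees: 8-bit bright-field frames (80 x 250 px by default) of cells flowing
through a narrow channel, with

* a flat background at a session-dependent brightness (24-49 grayscale),
  plus a *static* sensor-noise pattern (sd ~ 2.9) that is identical in every
  frame of a session,
* dark channel walls at configurable rows,
* cells rendered as anisotropic blurred annuli — dark membrane rim, bright
  interior — with an optional tail lobe, tilted relative to the flow axis,
* event timestamps from a Poisson arrival process set by concentration and
  flow rate, with occasional cell *avalanches*: bursts of consecutive events
  spaced exactly one camera frame period apart,
* doublets: a second object attached or closer than 15 um.

Every stream carries full per-event ground truth (object count, centroids,
nearest-neighbour distance, area, tilt, fluorescence, class), so the whole
downstream pipeline is testable without any recorded data.

The generator is not a physical optics model: no diffraction, no
deformation mechanics, no fluorescence waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "SyntheticConfig",
    "ObjectSpec",
    "GroundTruth",
    "CropDataset",
    "PIXEL_SIZE_UM",
    "render_frame",
    "simulate_event_stream",
    "make_two_class_dataset",
    "make_doublet_dataset",
]

#: um per pixel: a 36 px crop spans 24.5 um.
PIXEL_SIZE_UM = 24.5 / 36.0

#: Doublet proximity rule: a second object closer than this is a doublet (um).
DOUBLET_DISTANCE_UM = 15.0

# half-normal: median = sd * Phi^-1(0.75); sd giving median 11 deg
_TILT_SD_FOR_MEDIAN_11 = 11.0 / 0.6744897501960817

# photometric body extent relative to the nominal object boundary; calibrated
# once so the reference segmentation recovers the nominal area unbiased
_BODY_EXTENT = 0.83


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults are the instrument's operating point."""

    frame_height: int = 80
    frame_width: int = 250
    pixel_size: float = PIXEL_SIZE_UM        # um/px
    frame_rate: float = 3000.0               # frames/s
    background_level: float = 39.0           # grayscale, sessions span 24-49
    background_noise_sd: float = 2.9         # static pattern sd, grayscale
    sample_concentration: float = 20e6       # cells/ml before sheath dilution
    flow_sample: float = 0.01                # ul/s
    flow_sheath: float = 0.03                # ul/s
    doublet_fraction: float = 0.10
    avalanche_rate: float = 0.05             # bursts/s
    avalanche_length: float = 10.0           # mean events per burst
    tilt_sd: float = _TILT_SD_FOR_MEDIAN_11  # deg; abs(Normal) median ~ 11 deg
    area_range: tuple[float, float] = (20.0, 35.0)  # um^2
    wall_rows: tuple[int, int] | None = (14, 66)    # channel wall rows
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.doublet_fraction <= 1.0:
            raise ValueError("doublet_fraction must be a probability")
        for name in ("sample_concentration", "avalanche_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frame_rate", "flow_sample", "flow_sheath", "pixel_size",
                     "tilt_sd", "avalanche_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if not self.area_range[0] < self.area_range[1]:
            raise ValueError("area_range must be increasing")
        if abs(self.pixel_size * 36.0 - 24.5) > 0.5:
            raise ValueError("pixel_size inconsistent with 36 px = 24.5 um crop geometry")

    @property
    def flow_total(self) -> float:
        return self.flow_sample + self.flow_sheath

    @property
    def event_rate(self) -> float:
        """Expected events/s: diluted concentration x total flow."""
        channel_conc = self.sample_concentration * self.flow_sample / self.flow_total
        return channel_conc * self.flow_total * 1e-3  # ul -> ml

    def static_noise(self) -> np.ndarray:
        """The session's fixed sensor-noise pattern (same in every frame)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x5A71C]))
        return rng.normal(0.0, self.background_noise_sd,
                          (self.frame_height, self.frame_width))


@dataclass(frozen=True)
class ObjectSpec:
    """One rendered cell: bullet-shaped annulus with optional tail lobe."""

    row: float                 # centroid, px
    col: float                 # centroid, px
    area_um2: float
    tilt_deg: float = 0.0      # orientation vs flow axis (columns)
    aspect: float = 1.3        # major/minor axis ratio
    rim_depth: float = 40.0    # grayscale drop of the membrane ring
    core_gain: float = 25.0    # grayscale lift of the interior
    tail: bool = False         # trailing lobe (neural-process-like)

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        if self.aspect < 1.0:
            raise ValueError("aspect must be >= 1")


def _elliptic_radius(shape: tuple[int, int], obj: ObjectSpec,
                     pixel_size: float) -> np.ndarray:
    """Normalised elliptical radius field (1.0 on the object boundary)."""
    area_px = obj.area_um2 / pixel_size ** 2
    a = math.sqrt(area_px * obj.aspect / math.pi)   # semi-major, px
    b = math.sqrt(area_px / (obj.aspect * math.pi))  # semi-minor, px
    rows = np.arange(shape[0])[:, None] - obj.row
    cols = np.arange(shape[1])[None, :] - obj.col
    th = math.radians(obj.tilt_deg)
    # major axis along flow (columns) rotated by tilt; image rows grow downward
    u = cols * math.cos(th) - rows * math.sin(th)
    v = cols * math.sin(th) + rows * math.cos(th)
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def render_frame(config: SyntheticConfig, objects: Sequence[ObjectSpec],
                 rng: np.random.Generator | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame; returns (uint8 image, boolean object mask).

    image = background level + static noise pattern + channel walls
    + object renderings, clipped to [0, 255].  Rendering is fully
    deterministic for a given config and object list; ``rng`` only seeds a
    faint interior texture and may be omitted.
    """
    shape = (config.frame_height, config.frame_width)
    for obj in objects:
        if not (0 <= obj.row < shape[0] and 0 <= obj.col < shape[1]):
            raise ValueError(
                f"object centroid ({obj.row}, {obj.col}) outside frame {shape}")
    img = np.full(shape, config.background_level, dtype=float)
    img += config.static_noise()
    if config.wall_rows is not None:
        for r in config.wall_rows:
            img[max(r - 1, 0):r + 1, :] -= 18.0
    mask = np.zeros(shape, dtype=bool)
    for obj in objects:
        r = _elliptic_radius(shape, obj, config.pixel_size)
        # whole body below background, rim darkest, interior relatively
        # bright: keeps the thresholded body contiguous, as real slightly
        # defocused bright-field cells are.  The photometric body sits at
        # _BODY_EXTENT of the nominal boundary so that the reference
        # segmentation (threshold 6, 1 erode + 1 dilate) recovers the
        # nominal area without bias; the ground-truth mask keeps r <= 1.
        body = np.zeros(shape)
        body[r <= _BODY_EXTENT] -= obj.rim_depth
        body[r <= 0.6 * _BODY_EXTENT] += obj.core_gain
        if obj.tail:
            tail_obj = replace(
                obj,
                col=min(shape[1] - 1.0,
                        obj.col + 0.9 * math.sqrt(obj.area_um2) / config.pixel_size),
                area_um2=obj.area_um2 * 0.25, aspect=2.0, tail=False)
            rt = _elliptic_radius(shape, tail_obj, config.pixel_size)
            body[rt <= 1.0] -= 0.5 * obj.rim_depth
        if rng is not None:
            texture = rng.normal(0.0, 2.0, shape)
            core = r <= 0.6 * _BODY_EXTENT
            body[core] += texture[core]
        img += ndimage.gaussian_filter(body, sigma=0.8)
        mask |= r <= 1.0 + 1e-9  # boundary pixels belong to the object
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask


@dataclass(frozen=True)
class GroundTruth:
    """Per-event ground truth emitted alongside each synthetic frame."""

    timestamp: float                     # s
    n_objects: int
    object_centroids: tuple[tuple[float, float], ...]  # (row, col) px
    nearest_neighbor_um: float           # inf when no second object nearby
    true_area_um2: float                 # primary object
    true_tilt_deg: float                 # primary object, absolute
    fluorescence: float                  # a.u.
    cell_class: str                      # "A" (reporter-positive-like) or "B"
    in_avalanche: bool

    @property
    def is_doublet(self) -> bool:
        """Doublet iff multiple objects or a neighbour closer than 15 um."""
        return self.n_objects > 1 or self.nearest_neighbor_um < DOUBLET_DISTANCE_UM


def _draw_objects(config: SyntheticConfig, rng: np.random.Generator,
                  doublet: bool) -> tuple[list[ObjectSpec], float, str, float]:
    """Sample the object(s) of one event; returns (objects, nn_um, class, fluor)."""
    lo, hi = config.area_range
    area = rng.uniform(lo, hi)
    tilt = rng.normal(0.0, config.tilt_sd)
    if config.wall_rows is not None:
        row_lo, row_hi = config.wall_rows[0] + 8, config.wall_rows[1] - 8
    else:
        row_lo, row_hi = 12, config.frame_height - 12
    row = rng.uniform(row_lo, row_hi)
    col = rng.uniform(0.3 * config.frame_width, 0.7 * config.frame_width)
    cell_class = "A" if rng.random() < 0.5 else "B"
    # fluorescence: lognormal clouds around ~4000 (positive) / ~300 (negative)
    if cell_class == "A":
        fluor = float(rng.lognormal(math.log(4000.0), 0.45))
    else:
        fluor = float(rng.lognormal(math.log(300.0), 0.55))
    primary = ObjectSpec(row=row, col=col, area_um2=area, tilt_deg=tilt,
                         tail=bool(rng.random() < 0.3))
    objects = [primary]
    nn_um = math.inf
    if doublet:
        dist_um = rng.uniform(4.0, DOUBLET_DISTANCE_UM - 1.0)
        ang = rng.uniform(0.0, 2.0 * math.pi)
        d_px = dist_um / config.pixel_size
        row2 = min(max(row + d_px * math.sin(ang), 1.0), config.frame_height - 2.0)
        col2 = min(max(col + d_px * math.cos(ang), 1.0), config.frame_width - 2.0)
        nn_um = math.hypot(row2 - row, col2 - col) * config.pixel_size
        objects.append(ObjectSpec(row=row2, col=col2,
                                  area_um2=rng.uniform(lo, hi),
                                  tilt_deg=rng.normal(0.0, config.tilt_sd)))
    return objects, nn_um, cell_class, fluor


def _event_times(config: SyntheticConfig, duration: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Arrival times: Poisson background plus exactly frame-spaced bursts.

    Returns (times, in_avalanche flags), strictly increasing; events closer
    than half a frame period to a predecessor are dropped (the camera
    captures at most one event per frame).
    """
    n_normal = rng.poisson(config.event_rate * duration)
    times = [np.sort(rng.uniform(0.0, duration, n_normal))]
    flags = [np.zeros(n_normal, dtype=bool)]
    n_bursts = rng.poisson(config.avalanche_rate * duration)
    dt = 1.0 / config.frame_rate
    for start in rng.uniform(0.0, duration, n_bursts):
        # geometric burst length, truncated so every burst is detectable
        length = max(4, int(rng.geometric(1.0 / config.avalanche_length)))
        burst = start + dt * np.arange(length)
        times.append(burst)
        flags.append(np.ones(length, dtype=bool))
    t = np.concatenate(times)
    f = np.concatenate(flags)
    order = np.argsort(t, kind="stable")
    t, f = t[order], f[order]
    if t.size:  # exact ties have probability zero but must not survive
        keep = np.concatenate([[True], np.diff(t) > 0.0])
        t, f = t[keep], f[keep]
    return t, f


def simulate_event_stream(config: SyntheticConfig, duration: float,
                          rng: np.random.Generator,
                          render: bool = True,
                          ) -> tuple[list[np.ndarray] | None, list[GroundTruth]]:
    """Simulate ``duration`` seconds of acquisition.

    Normal events arrive as a Poisson process at the rate implied by the
    channel concentration and total flow; avalanches are superimposed bursts
    of consecutive events spaced exactly one frame period apart.  With
    ``render=False`` only ground truth is produced (cheap, for long runs).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    times, burst_flags = _event_times(config, duration, rng)
    frames: list[np.ndarray] | None = [] if render else None
    truths: list[GroundTruth] = []
    for ts, in_burst in zip(times, burst_flags):
        doublet = rng.random() < config.doublet_fraction
        objects, nn_um, cell_class, fluor = _draw_objects(config, rng, doublet)
        if render:
            frame, _ = render_frame(config, objects, rng)
            frames.append(frame)
        truths.append(GroundTruth(
            timestamp=float(ts),
            n_objects=len(objects),
            object_centroids=tuple((o.row, o.col) for o in objects),
            nearest_neighbor_um=nn_um,
            true_area_um2=objects[0].area_um2,
            true_tilt_deg=abs(objects[0].tilt_deg),
            fluorescence=fluor,
            cell_class=cell_class,
            in_avalanche=bool(in_burst),
        ))
    return frames, truths


@dataclass
class CropDataset:
    """Labelled crop dataset: images, binary labels, fluorescence, groups.

    ``groups`` partitions samples into per-measurement (session) groups to
    exercise balanced sampling across sessions.
    """

    images: np.ndarray        # (N, size, size) uint8
    labels: np.ndarray        # (N,) int, 0/1
    fluorescence: np.ndarray  # (N,) float
    groups: np.ndarray        # (N,) int

    def __len__(self) -> int:
        return len(self.labels)


def _crop_config(config: SyntheticConfig, size: int,
                 background_level: float) -> SyntheticConfig:
    return replace(config, frame_height=size, frame_width=size,
                   wall_rows=None, background_level=background_level)


def make_two_class_dataset(config: SyntheticConfig, n_per_class: int,
                           rng: np.random.Generator, effect: float = 1.0,
                           crop_size: int = 36, n_measurements: int = 3,
                           session_spread: float = 3.0) -> CropDataset:
    """Two morphology classes of single-cell crops, balanced labels.

    Both classes live in the same area band; class 1 differs from class 0 by
    an ``effect``-scaled morphology shift — brighter interior, shallower
    membrane rim (texture contrast) and higher eccentricity (at ``effect=0``
    the classes are generatively identical and no classifier can beat
    chance).  Fluorescence is correlated with the class label.  Samples are
    split round-robin into ``n_measurements`` groups whose background
    brightness differs by ``session_spread`` grayscale across groups,
    mimicking session-to-session drift within one study (the full 24-49
    between-experiment range is much wider and is covered by augmentation,
    not within a single dataset).
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    n = 2 * n_per_class
    labels = np.tile([0, 1], n_per_class)
    groups = np.arange(n) % n_measurements
    bg0 = config.background_level
    session_bg = (np.linspace(-0.5, 0.5, n_measurements) * session_spread + bg0
                  if n_measurements > 1 else np.array([bg0]))
    images = np.empty((n, crop_size, crop_size), dtype=np.uint8)
    fluor = np.empty(n)
    lo, hi = config.area_range
    center = (crop_size - 1) / 2.0
    for i in range(n):
        label = labels[i]
        ccfg = _crop_config(config, crop_size, session_bg[groups[i]])
        obj = ObjectSpec(
            row=center + rng.uniform(-1.5, 1.5),
            col=center + rng.uniform(-1.5, 1.5),
            area_um2=rng.uniform(lo, hi),
            tilt_deg=rng.normal(0.0, config.tilt_sd),
            aspect=1.15 + (0.45 * effect if label else 0.0),
            core_gain=min(25.0 + (18.0 * effect if label else 0.0), 60.0),
            rim_depth=max(40.0 - (12.0 * effect if label else 0.0), 8.0),
            tail=bool(rng.random() < 0.3),
        )
        images[i], _ = render_frame(ccfg, [obj], rng)
        mean_f = 4000.0 if label else 300.0
        fluor[i] = rng.lognormal(math.log(mean_f), 0.5)
    return CropDataset(images, labels.astype(int), fluor, groups)


def make_doublet_dataset(config: SyntheticConfig, n_per_class: int,
                         rng: np.random.Generator, crop_size: int = 36,
                         separation_um: tuple[float, float] = (1.0, 12.0),
                         tail_fraction: float = 0.3) -> CropDataset:
    """Single-vs-doublet crop dataset (label 1 = doublet).

    Doublets place a second cell attached (overlapping bodies) or at a
    proximity drawn from ``separation_um``; singles are isolated.  The
    default separation tops out at 12 um: a 36 px crop spans +-12.25 um
    from the cell centre, so a farther neighbour leaves the field of view
    and the image no longer determines the label (the 15 um ground-truth
    proximity rule itself is unchanged).  ``tail_fraction`` of cells carry
    a tail lobe, the morphology most confusable with an attached doublet.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    n = 2 * n_per_class
    labels = np.tile([0, 1], n_per_class)
    groups = np.zeros(n, dtype=int)
    images = np.empty((n, crop_size, crop_size), dtype=np.uint8)
    fluor = np.empty(n)
    lo, hi = config.area_range
    center = (crop_size - 1) / 2.0
    ccfg = _crop_config(config, crop_size, config.background_level)
    for i in range(n):
        objects = [ObjectSpec(
            row=center + rng.uniform(-1.5, 1.5),
            col=center + rng.uniform(-1.5, 1.5),
            area_um2=rng.uniform(lo, hi),
            tilt_deg=rng.normal(0.0, config.tilt_sd),
            tail=bool(rng.random() < tail_fraction),
        )]
        if labels[i]:
            dist_um = rng.uniform(*separation_um)
            ang = rng.uniform(0.0, 2.0 * math.pi)
            d_px = dist_um / config.pixel_size
            o = objects[0]
            objects.append(ObjectSpec(
                row=float(np.clip(o.row + d_px * math.sin(ang), 1, crop_size - 2)),
                col=float(np.clip(o.col + d_px * math.cos(ang), 1, crop_size - 2)),
                area_um2=rng.uniform(lo, hi),
                tilt_deg=rng.normal(0.0, config.tilt_sd),
            ))
        images[i], _ = render_frame(ccfg, objects, rng)
        fluor[i] = rng.lognormal(math.log(1000.0), 0.5)
    return CropDataset(images, labels.astype(int), fluor, groups)
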