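"""HDF5 event container: the on-disk interchange format.

Mirrors the per-event layout customary in the deformability-cytometry
ecosystem (one dataset per feature under ``/events``, acquisition metadata
as root attributes), without claiming full dialect parity with the .rtdc
format.  Synthetic ground truth, when present, lives under ``/labels`` and
is preserved on round trips.

Layout::

    /events/image         (N, H, W) uint8
    /events/time          (N,) float64, seconds, non-decreasing
    /events/fluorescence  (N,) float64, a.u.
    /events/area_um2      (N,) float64          } optional,
    /events/tilt_deg      (N,) float64          } filled by analysis
    /events/n_contours    (N,) int32            }
    /events/p_doublet     (N,) float64          }
    /labels/...           ground truth (synthetic streams only)
    attrs: pixel_size_um, frame_rate_fps, flow_sample_ul_s,
           flow_sheath_ul_s, schema_version
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["EventContainer", "SchemaError", "write_container", "read_container"]

SCHEMA_VERSION = "1.0"

_MANDATORY_ATTRS = ("pixel_size_um", "frame_rate_fps",
                    "flow_sample_ul_s", "flow_sheath_ul_s")
_OPTIONAL_EVENT_KEYS = ("area_um2", "tilt_deg", "n_contours", "p_doublet")


class SchemaError(ValueError):
    """A container file violates the event-container schema."""


@dataclass
class EventContainer:
    """In-memory event container; all per-event arrays share length N."""

    images: np.ndarray         # (N, H, W) uint8
    times: np.ndarray          # (N,) s
    fluorescence: np.ndarray   # (N,) a.u.
    pixel_size_um: float
    frame_rate_fps: float
    flow_sample_ul_s: float
    flow_sheath_ul_s: float
    features: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return self.images.shape[0]

    def validate(self) -> None:
        if self.images.ndim != 3:
            raise SchemaError("/events/image must be (N, H, W)")
        n = self.images.shape[0]
        for name, arr in (("time", self.times),
                          ("fluorescence", self.fluorescence)):
            if arr.shape != (n,):
                raise SchemaError(
                    f"/events/{name} has length {arr.shape}, expected ({n},)")
        for group in (self.features, self.labels):
            for name, arr in group.items():
                if np.asarray(arr).shape[0] != n:
                    raise SchemaError(f"dataset {name} has mismatched length")
        if n and np.any(np.diff(self.times) < 0):
            raise SchemaError("/events/time must be non-decreasing")
        if self.pixel_size_um <= 0:
            raise SchemaError("pixel_size_um must be positive")


def write_container(path: str | Path, container: EventContainer,
                    overwrite: bool = False) -> Path:
    """Write a validated container to HDF5; refuses silent overwrites."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists (pass overwrite=True)")
    container.validate()
    with h5py.File(path, "w") as f:
        ev = f.create_group("events")
        ev.create_dataset("image", data=container.images)
        ev.create_dataset("time", data=container.times)
        ev.create_dataset("fluorescence", data=container.fluorescence)
        for name, arr in container.features.items():
            ev.create_dataset(name, data=np.asarray(arr))
        if container.labels:
            lab = f.create_group("labels")
            for name, arr in container.labels.items():
                arr = np.asarray(arr)
                if arr.dtype.kind in "US":
                    arr = arr.astype(h5py.string_dtype())
                lab.create_dataset(name, data=arr)
        f.attrs["pixel_size_um"] = container.pixel_size_um
        f.attrs["frame_rate_fps"] = container.frame_rate_fps
        f.attrs["flow_sample_ul_s"] = container.flow_sample_ul_s
        f.attrs["flow_sheath_ul_s"] = container.flow_sheath_ul_s
        f.attrs["schema_version"] = SCHEMA_VERSION
    return path


def read_container(path: str | Path) -> EventContainer:
    """Read and validate an event container; unknown datasets are preserved."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in _MANDATORY_ATTRS + ("schema_version",):
            if attr not in f.attrs:
                raise SchemaError(f"missing root attribute {attr!r}")
        if "events" not in f:
            raise SchemaError("missing /events group")
        ev = f["events"]
        for name in ("image", "time", "fluorescence"):
            if name not in ev:
                raise SchemaError(f"missing mandatory dataset /events/{name}")
        images = ev["image"][()]
        if images.ndim != 3:
            raise SchemaError("/events/image must be (N, H, W)")
        features = {name: ev[name][()] for name in ev
                    if name not in ("image", "time", "fluorescence")}
        labels = {}
        if "labels" in f:
            for name in f["labels"]:
                arr = f["labels"][name][()]
                if arr.dtype.kind == "O":
                    arr = arr.astype(str)
                labels[name] = arr
        return EventContainer(
            images=images,
            times=ev["time"][()],
            fluorescence=ev["fluorescence"][()],
            pixel_size_um=float(f.attrs["pixel_size_um"]),
            frame_rate_fps=float(f.attrs["frame_rate_fps"]),
            flow_sample_ul_s=float(f.attrs["flow_sample_ul_s"]),
            flow_sheath_ul_s=float(f.attrs["flow_sheath_ul_s"]),
            features=features,
            labels=labels,
        )
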