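"""MLP architecture screening under a CPU latency budget.

Sorting requires a single-image inference time below the actuation budget
(sub-250 us), which rules out convolutional nets on CPU.  The screen
enumerates fully-connected architectures (1-4 hidden layers, widths a
multiple of 8 from 8 to 240), counts trainable parameters, optionally times
single-image inference, and selects the largest model inside a latency band.

Two parameter counts appear:

* :func:`count_params` — the full trainable-parameter count (weights and
  biases of every layer including the output layer).  With input 324
  (18x18 pixels) and a 4-unit output this reproduces the reference counts
  8,708 / 78,964 / 39,284 / 23,396 for the published architectures.
* :func:`hidden_weight_count` — the screening complexity metric: inter-layer
  weights up to the last hidden layer only (324*n1 + sum n_i*n_{i+1}), no
  biases, no output layer.  The published enumeration split
  (30 / 671 / 16,527 / 379,293 architectures surviving an 80,000-parameter
  budget for k = 1..4) is reproduced exactly only by a strict cut on this
  metric; the enumeration therefore filters on it by default.

Absolute inference times are hardware-dependent and are never used as fixed
expectations; only the measurement protocol is contract-tested.
"""

from __future__ import annotations

import itertools
import platform
import time
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MLPArchitecture",
    "ScreenRecord",
    "TimingProtocol",
    "count_params",
    "hidden_weight_count",
    "default_width_grid",
    "enumerate_archs",
    "enumeration_counts",
    "measure_inference",
    "select_in_band",
    "records_to_frame",
]

DEFAULT_INPUT_DIM = 324   # 18 x 18 crop
DEFAULT_OUTPUT_DIM = 4
DEFAULT_PARAM_CAP = 80_000


@dataclass(frozen=True)
class MLPArchitecture:
    """Fully-connected classifier: input -> k ReLU hidden layers -> softmax."""

    hidden_widths: tuple[int, ...]
    input_dim: int = DEFAULT_INPUT_DIM
    output_dim: int = DEFAULT_OUTPUT_DIM

    def __post_init__(self) -> None:
        if len(self.hidden_widths) < 1:
            raise ValueError("at least one hidden layer is required")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ValueError("input/output dims must be positive")
        object.__setattr__(self, "hidden_widths", tuple(int(w) for w in self.hidden_widths))

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_widths)

    @property
    def layer_dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_widths, self.output_dim)


def count_params(arch: MLPArchitecture) -> int:
    """Exact trainable-parameter count: sum of (d_in + 1) * d_out per layer."""
    dims = arch.layer_dims
    return int(sum((a + 1) * b for a, b in zip(dims[:-1], dims[1:])))


def hidden_weight_count(arch: MLPArchitecture) -> int:
    """Screening complexity metric: hidden-layer weights only, no biases."""
    dims = (arch.input_dim, *arch.hidden_widths)
    return int(sum(a * b for a, b in zip(dims[:-1], dims[1:])))


@dataclass
class ScreenRecord:
    """One screened architecture with its size and (optional) latency."""

    architecture: MLPArchitecture
    n_params: int
    inference_time_us: float | None = None

    @property
    def n_hidden(self) -> int:
        return self.architecture.n_hidden


def default_width_grid() -> tuple[int, ...]:
    """Widths screened per hidden layer: multiples of 8 from 8 to 240."""
    return tuple(range(8, 241, 8))


def _survivor_widths(k: int, grid: Sequence[int], param_cap: int,
                     input_dim: int) -> np.ndarray:
    """Width combinations for k hidden layers passing the complexity cap.

    Vectorised over the full grid^k cross product; the cap is a strict cut
    on the hidden-weight metric.  Rows come out in lexicographic grid order.
    """
    g = np.asarray(sorted(grid), dtype=np.int64)
    combos = np.stack(np.meshgrid(*([g] * k), indexing="ij"), axis=-1).reshape(-1, k)
    metric = input_dim * combos[:, 0]
    for i in range(k - 1):
        metric = metric + combos[:, i] * combos[:, i + 1]
    return combos[metric < param_cap]


def enumerate_archs(k_min: int = 1, k_max: int = 4,
                    width_grid: Sequence[int] | None = None,
                    param_cap: int = DEFAULT_PARAM_CAP,
                    input_dim: int = DEFAULT_INPUT_DIM,
                    output_dim: int = DEFAULT_OUTPUT_DIM) -> list[ScreenRecord]:
    """Enumerate all surviving architectures, ordered by (k, widths).

    ``n_params`` on each record is the full trainable count; the cap itself
    is applied to the hidden-weight complexity metric (see module docstring).
    At the defaults this yields 396,521 records.
    """
    if width_grid is None:
        width_grid = default_width_grid()
    if not width_grid:
        raise ValueError("width grid must be non-empty")
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    records: list[ScreenRecord] = []
    for k in range(k_min, k_max + 1):
        for widths in _survivor_widths(k, width_grid, param_cap, input_dim):
            arch = MLPArchitecture(tuple(int(w) for w in widths),
                                   input_dim=input_dim, output_dim=output_dim)
            records.append(ScreenRecord(arch, count_params(arch)))
    return records


def enumeration_counts(k_min: int = 1, k_max: int = 4,
                       width_grid: Sequence[int] | None = None,
                       param_cap: int = DEFAULT_PARAM_CAP,
                       input_dim: int = DEFAULT_INPUT_DIM) -> dict[int, int]:
    """Survivor count per hidden-layer count, without building records.

    Same filter as :func:`enumerate_archs`, evaluated vectorised; at the
    defaults: {1: 30, 2: 671, 3: 16527, 4: 379293}.
    """
    if width_grid is None:
        width_grid = default_width_grid()
    return {k: int(len(_survivor_widths(k, width_grid, param_cap, input_dim)))
            for k in range(k_min, k_max + 1)}


@dataclass(frozen=True)
class TimingProtocol:
    """Single-image inference timing protocol.

    One pre-heat forward wakes the CPU from power-saving throttle and is
    excluded from the average; then ``images_per_rep`` images are forwarded
    individually (not batched), repeated ``reps`` times.
    """

    preheat_forwards: int = 1
    images_per_rep: int = 500
    reps: int = 10

    def __post_init__(self) -> None:
        if min(self.preheat_forwards, self.images_per_rep, self.reps) <= 0:
            raise ValueError("all protocol counts must be positive")


def measure_inference(evaluator: Callable[[np.ndarray], object],
                      protocol: TimingProtocol = TimingProtocol(),
                      image_shape: tuple[int, ...] = (18, 18),
                      rng: np.random.Generator | None = None) -> dict:
    """Measure mean single-image inference time in microseconds.

    Returns a dict with ``mean_us``, per-rep times ``rep_us``, and machine
    metadata.  Times are valid only for the measuring hardware and power
    settings; they are never comparable across machines.
    """
    rng = rng or np.random.default_rng()
    images = rng.random((protocol.images_per_rep, *image_shape))
    for _ in range(protocol.preheat_forwards):
        evaluator(images[0])
    rep_us = []
    for _ in range(protocol.reps):
        t0 = time.perf_counter()
        for img in images:
            evaluator(img)
        rep_us.append((time.perf_counter() - t0) / protocol.images_per_rep * 1e6)
    return {
        "mean_us": float(np.mean(rep_us)),
        "rep_us": rep_us,
        "machine": platform.processor() or platform.machine(),
        "python": platform.python_version(),
    }


def select_in_band(records: Iterable[ScreenRecord], t_low: float,
                   t_high: float) -> dict[int, ScreenRecord]:
    """Per hidden-layer count, the max-parameter record inside a latency band.

    Only records carrying an inference time are considered.  Ties on
    n_params break toward fewer layers, then lexicographically smaller
    widths.  Layer counts with no record in [t_low, t_high] are absent from
    the result.
    """
    best: dict[int, ScreenRecord] = {}
    for rec in records:
        t = rec.inference_time_us
        if t is None or not (t_low <= t <= t_high):
            continue
        k = rec.n_hidden
        cur = best.get(k)
        if cur is None:
            best[k] = rec
            continue
        key = (-rec.n_params, rec.n_hidden, rec.architecture.hidden_widths)
        cur_key = (-cur.n_params, cur.n_hidden, cur.architecture.hidden_widths)
        if key < cur_key:
            best[k] = rec
    return best


def records_to_frame(records: Iterable[ScreenRecord]) -> pd.DataFrame:
    """Flatten screen records to a DataFrame (k, widths, n_params, time)."""
    rows = [{
        "k": r.n_hidden,
        "widths": "x".join(map(str, r.architecture.hidden_widths)),
        "n_params": r.n_params,
        "inference_time_us": r.inference_time_us,
    } for r in records]
    return pd.DataFrame(rows, columns=["k", "widths", "n_params", "inference_time_us"])
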