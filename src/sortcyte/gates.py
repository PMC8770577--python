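"""Aggregate suppression gates and Poisson coincidence planning.

During image-activated sorting, the acoustic pulse deflects everything inside
the sorting region for its whole duration (2 ms by default).  Two failure
modes must be suppressed:

* **coincidence** — more than one cell happens to occupy the pulse volume.
  Cell arrivals are (to first order) independent, so the count in a pulse
  volume is Poisson; the planner maps sample concentration to the expected
  count mu and the coincidence probability 1 - p(0) - p(1).
* **avalanches** — clumps of cells traverse the channel back-to-back, one per
  camera frame, violating the independence assumption.  These are recognised
  by inter-event gaps equal to the frame period, and suppressed by a
  minimum-inter-event-time gate (and by refusing to sort frames with more
  than one detected contour).

Units: flows in ul/s, concentrations in cells/ml, volumes in nl, times in s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FlowConfig",
    "PoissonPlan",
    "TimingGate",
    "pulse_volume_nl",
    "channel_concentration",
    "poisson_pmf",
    "prob_multiple",
    "event_rate",
    "free_spacing_um",
    "make_plan",
    "plan_table",
    "contour_count_gate",
    "timing_gate",
    "detect_avalanches",
]

ML_PER_NL = 1e-6
UM3_PER_ML = 1e12


@dataclass(frozen=True)
class FlowConfig:
    """Chip flow settings.

    The sheath flow hydrodynamically focusses the sample stream, so the cell
    concentration inside the channel is the sample concentration diluted by
    Q_sample / Q_total.  The channel cross-section default (20 um x 20 um =
    400 um^2) is a derived constant, configurable.
    """

    flow_sample: float = 0.01        # ul/s
    flow_sheath: float = 0.03        # ul/s
    pulse_duration: float = 0.002    # s
    frame_rate: float = 3000.0       # frames/s
    channel_cross_section: float = 400.0  # um^2

    def __post_init__(self) -> None:
        for name in ("flow_sample", "flow_sheath", "frame_rate",
                     "channel_cross_section"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pulse_duration < 0:  # 0 allowed (degenerate instantaneous pulse)
            raise ValueError("pulse_duration must be non-negative")

    @property
    def flow_total(self) -> float:
        """Q_total = Q_sample + Q_sheath, ul/s."""
        return self.flow_sample + self.flow_sheath


def pulse_volume_nl(flow: FlowConfig) -> float:
    """Volume passing the chip during one sorting pulse, in nl.

    Q_total [ul/s] x pulse_duration [s]; 0.04 ul/s x 2 ms = 0.08 nl.
    """
    return flow.flow_total * flow.pulse_duration * 1e3  # ul -> nl


def channel_concentration(sample_concentration: float, flow: FlowConfig) -> float:
    """Cell concentration inside the channel after sheath dilution (cells/ml)."""
    if sample_concentration < 0:
        raise ValueError("sample concentration must be non-negative")
    return sample_concentration * flow.flow_sample / flow.flow_total


def poisson_pmf(n: int | np.ndarray, mu: float) -> float | np.ndarray:
    """p(n) = mu^n e^-mu / n!, the chance of n cells in one pulse volume."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return stats.poisson.pmf(n, mu)


def prob_multiple(mu: float) -> float:
    """Probability of more than one cell in the pulse volume: 1 - e^-mu (1 + mu)."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    return -np.expm1(-mu) - mu * np.exp(-mu)


def event_rate(sample_concentration: float, flow: FlowConfig) -> float:
    """Expected measurement frequency in cells/s.

    channel concentration [cells/ml] x Q_total [ul/s -> ml/s].
    """
    conc = channel_concentration(sample_concentration, flow)
    return conc * flow.flow_total * 1e-3  # ul -> ml


def free_spacing_um(sample_concentration: float, flow: FlowConfig,
                    cell_diameter: float = 10.0) -> float:
    """Average free space between consecutive cells along the channel (um).

    One cell occupies 1 / (channel concentration x cross-section) of channel
    length; subtracting the cell diameter leaves the free gap.  Returns 0
    with a crowding warning when cells would touch.
    """
    if sample_concentration <= 0:
        raise ValueError("sample concentration must be positive")
    if cell_diameter <= 0:
        raise ValueError("cell diameter must be positive")
    conc_per_um3 = channel_concentration(sample_concentration, flow) / UM3_PER_ML
    spacing = 1.0 / (conc_per_um3 * flow.channel_cross_section) - cell_diameter
    if spacing < 0:
        import warnings
        warnings.warn("cells are crowded: spacing below one cell diameter",
                      stacklevel=2)
        return 0.0
    return spacing


@dataclass(frozen=True)
class PoissonPlan:
    """Planner output for one sample concentration."""

    sample_concentration: float   # cells/ml
    channel_concentration: float  # cells/ml
    pulse_volume: float           # nl
    mu: float                     # expected cells per pulse volume
    p_multiple: float             # probability of >1 cell per pulse
    rate: float                   # events/s
    free_spacing: float           # um


def make_plan(sample_concentration: float, flow: FlowConfig | None = None,
              cell_diameter: float = 10.0) -> PoissonPlan:
    """Full planning chain: dilution -> pulse volume -> Poisson coincidence."""
    flow = flow or FlowConfig()
    conc = channel_concentration(sample_concentration, flow)
    vol = pulse_volume_nl(flow)
    mu = conc * vol * ML_PER_NL
    return PoissonPlan(
        sample_concentration=sample_concentration,
        channel_concentration=conc,
        pulse_volume=vol,
        mu=mu,
        p_multiple=float(prob_multiple(mu)),
        rate=event_rate(sample_concentration, flow),
        free_spacing=free_spacing_um(sample_concentration, flow, cell_diameter),
    )


def plan_table(sample_concentrations: Sequence[float],
               flow: FlowConfig | None = None,
               cell_diameter: float = 10.0) -> pd.DataFrame:
    """Planner table over a range of concentrations (one row per value)."""
    plans = [make_plan(c, flow, cell_diameter) for c in sample_concentrations]
    return pd.DataFrame([vars(p) for p in plans])


# --------------------------------------------------------------------------
# real-time gates

def contour_count_gate(n_contours: int) -> bool:
    """Allow sorting only when exactly one contour was detected.

    Zero contours means nothing to sort; more than one means a potential
    aggregate or coincident cells in the field of view.
    """
    if n_contours < 0:
        raise ValueError("contour count cannot be negative")
    return n_contours == 1


@dataclass(frozen=True)
class TimingGate:
    """Minimum inter-event-time gate state.

    Events whose gap to the previous event falls below ``delta_t_min``
    (default 0.38 ms, just above the 1/3000 s frame period) are suppressed;
    the boundary is inclusive (gap == delta_t_min is allowed).  The last
    event time is updated on every event, allowed or not, so a whole
    avalanche stays suppressed.
    """

    delta_t_min: float = 0.00038  # s
    last_event_time: float = -np.inf

    def __post_init__(self) -> None:
        if self.delta_t_min <= 0:
            raise ValueError("delta_t_min must be positive")


def timing_gate(t_now: float, gate: TimingGate) -> tuple[bool, TimingGate]:
    """Apply the inter-event-time gate; returns (allow, updated gate)."""
    if t_now < gate.last_event_time:
        raise ValueError(
            f"non-monotone timestamps: {t_now} < {gate.last_event_time}")
    allow = (t_now - gate.last_event_time) >= gate.delta_t_min
    return allow, replace(gate, last_event_time=t_now)


def detect_avalanches(event_times: Sequence[float], frame_rate: float,
                      tolerance: float = 5e-5,
                      min_run: int = 3) -> list[tuple[int, int]]:
    """Find avalanche segments in a sorted event-time series.

    An avalanche is a maximal run of at least ``min_run`` consecutive
    inter-event gaps within ``tolerance`` of one frame period (1/frame_rate).
    Returns [start, stop) index pairs into ``event_times`` covering the
    events of each burst.
    """
    t = np.asarray(event_times, dtype=float)
    if t.ndim != 1:
        raise ValueError("event_times must be 1-D")
    if np.any(np.diff(t) < 0):
        raise ValueError("event_times must be sorted")
    if t.size < min_run + 1:
        return []
    gaps = np.diff(t)
    hit = np.abs(gaps - 1.0 / frame_rate) <= tolerance
    segments: list[tuple[int, int]] = []
    i = 0
    n = hit.size
    while i < n:
        if hit[i]:
            j = i
            while j < n and hit[j]:
                j += 1
            if j - i >= min_run:
                segments.append((i, j + 1))  # gaps i..j-1 span events i..j
            i = j
        else:
            i += 1
    return segments
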