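"""Pressure events -> digitized activations -> position/zone trace.

Each footstep pressure event is pushed through the sensor model (response
curve, voltage divider, threshold) to yield a per-quadrant activation level
plus the retained analog voltage.  Activations above threshold are then
matched against the spatial map to produce a timestamped (mat, quadrant)
position trace; mats carry zone labels from the room map.  All timestamps
are simulated minutes; conversion to real seconds happens only at the
interface layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .mapping import SpatialMap
from .scenarios import RoomMap, Trajectory
from .sensor import (DividerConfig, ResponseCurve, default_threshold,
                     digitize, divider_voltage)

__all__ = [
    "ActivationEvent",
    "ActivationStream",
    "PositionSample",
    "PositionTrace",
    "ZoneSample",
    "activations_from_pressures",
    "signal_matrix",
    "track",
    "zone_trace",
]

DEFAULT_DEBOUNCE_MINUTES = 2.0  # bridges the 0.5-min inter-step gaps


@dataclass(frozen=True)
class ActivationEvent:
    time: float
    address: int
    quadrant: int
    level: int        # 0 or 1
    volts: float      # retained analog value


@dataclass
class ActivationStream:
    events: list[ActivationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("activation events must be time-ordered")
        if any(not 0 <= e.quadrant < 4 for e in self.events):
            raise ValueError("quadrant index must be 0..3")


@dataclass(frozen=True)
class PositionSample:
    time: float
    address: int
    quadrant: int


@dataclass
class PositionTrace:
    samples: list[PositionSample] = field(default_factory=list)


@dataclass(frozen=True)
class ZoneSample:
    time: float
    address: int
    quadrant: int
    zone: Optional[str]


def activations_from_pressures(trajectory: Trajectory, curve: ResponseCurve,
                               divider: DividerConfig,
                               threshold: Optional[float] = None
                               ) -> ActivationStream:
    """Digitize a footstep stream through the sensor model.

    Each footstep drives exactly its own quadrant; unloaded quadrants emit
    nothing (they sit at the unloaded divider voltage, below threshold).
    """
    if threshold is None:
        threshold = default_threshold(curve, divider)
    events = []
    for fs in trajectory.footsteps:
        r = curve.resistance(fs.pressure, branch="loading")
        level, volts = digitize(divider_voltage(r, divider), threshold)
        events.append(ActivationEvent(time=fs.time, address=fs.address,
                                      quadrant=fs.quadrant, level=level,
                                      volts=volts))
    events.sort(key=lambda e: e.time)
    return ActivationStream(events=events)


def track(stream: ActivationStream, spatial_map: SpatialMap) -> PositionTrace:
    """Match above-threshold activations to mapped mats.

    Position at any instant is the active (mat, quadrant); simultaneous
    activations (double support) resolve to the most recent onset, i.e. the
    later event in the stream order.
    """
    known = set(spatial_map.entries)
    samples: list[PositionSample] = []
    for ev in stream.events:
        if ev.address not in known:
            raise KeyError(f"activation on unmapped address {ev.address}")
        if ev.level != 1:
            continue
        sample = PositionSample(time=ev.time, address=ev.address,
                                quadrant=ev.quadrant)
        if samples and samples[-1].time == ev.time:
            samples[-1] = sample  # latest onset wins at equal timestamps
        else:
            samples.append(sample)
    return PositionTrace(samples=samples)


def zone_trace(trace: PositionTrace, room: RoomMap) -> list[ZoneSample]:
    """Label each position sample with its mat's zone (None off-zone)."""
    return [ZoneSample(time=s.time, address=s.address, quadrant=s.quadrant,
                       zone=room.zone_of(s.address))
            for s in trace.samples]


def signal_matrix(stream: ActivationStream) -> pd.DataFrame:
    """Per-mat/quadrant analog signal table (for magnitude-vs-time plots)."""
    return pd.DataFrame(
        [{"time_min": e.time, "address": e.address, "quadrant": e.quadrant,
          "level": e.level, "volts": e.volts} for e in stream.events])
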