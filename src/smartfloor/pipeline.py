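"""End-to-end orchestration: script -> trajectory -> activations -> report.

The single entry point :func:`run_scenario` wires the full chain together
with one room and one seed, returning every intermediate artifact; it is
what the CLI subcommands and the reproduction script drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .behavior import AnalysisParams, BehaviorReport, analyze, match_accuracy
from .scenarios import (FIXTURE_N_MATS, GaitParams, RoomMap, ScenarioScript,
                        Trajectory, generate_trajectory, make_room,
                        script_scenario)
from .sensor import (DividerConfig, ResponseCurve, calibrate_response,
                     default_threshold)
from .tracking import (ActivationStream, PositionTrace, ZoneSample,
                       activations_from_pressures, track, zone_trace)

__all__ = ["ScenarioRun", "run_scenario"]


@dataclass
class ScenarioRun:
    """All artifacts of one scenario pipeline run."""

    room: RoomMap
    script: ScenarioScript
    trajectory: Trajectory
    stream: ActivationStream
    trace: PositionTrace
    zone_samples: list[ZoneSample]
    report: BehaviorReport
    truth: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.report.matching_accuracy


def run_scenario(name: str,
                 seed: int = 1,
                 room: Optional[RoomMap] = None,
                 n_mats: int = FIXTURE_N_MATS,
                 room_seed: Optional[int] = None,
                 curve: Optional[ResponseCurve] = None,
                 divider: Optional[DividerConfig] = None,
                 threshold: Optional[float] = None,
                 gait: GaitParams = GaitParams(),
                 params: AnalysisParams = AnalysisParams()) -> ScenarioRun:
    """Run one scenario end to end.

    The room defaults to the seeded fixture (57 mats); the sensor model
    defaults to the printed calibration (4.1 kOhm -> 0.25 kOhm over
    0-0.12 kg/cm^2, 5 V divider with a 1 kOhm load).
    """
    if room is None:
        room = make_room(n_mats=n_mats,
                         seed=seed if room_seed is None else room_seed)
    curve = curve or calibrate_response()
    divider = divider or DividerConfig()
    if threshold is None:
        threshold = default_threshold(curve, divider)

    script = script_scenario(name)
    trajectory = generate_trajectory(script, room, gait=gait, seed=seed)
    stream = activations_from_pressures(trajectory, curve, divider, threshold)
    trace = track(stream, room.spatial_map)
    samples = zone_trace(trace, room)
    report = analyze(samples, params)
    truth = script.truth()
    report.matching_accuracy = match_accuracy(report, truth)
    return ScenarioRun(room=room, script=script, trajectory=trajectory,
                       stream=stream, trace=trace, zone_samples=samples,
                       report=report, truth=truth)
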