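"""Plain-text serialization: JSONL event files, CSV tables, reports.

One JSON object per line for event streams (scripts, trajectories,
activations, traces); layout and zone tables as CSV; behavior reports as
JSON plus a key/value text rendering.  Writers are deterministic for a
given input (sorted keys, repr-round-trip floats), so identical seeds give
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

from .behavior import BehaviorReport
from .scenarios import Footstep, ScenarioScript, ScriptEvent, Trajectory
from .tracking import (ActivationEvent, ActivationStream, PositionSample,
                       PositionTrace, ZoneSample)

__all__ = [
    "read_script_jsonl", "read_trajectory_jsonl", "read_zone_trace_jsonl",
    "write_activations_jsonl", "write_report", "write_script_jsonl",
    "write_trace_jsonl", "write_trajectory_jsonl", "write_zone_trace_jsonl",
]


def _dump_lines(path, records: Iterable[dict]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def _load_lines(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_script_jsonl(path, script: ScenarioScript) -> None:
    header = {"kind": "script", "name": script.name,
              "total_duration": script.total_duration,
              "time_compression": script.time_compression,
              "sleep_window": list(script.sleep_window),
              "truth": script.truth()}
    _dump_lines(path, [header] + [
        {"kind": "event", **asdict(e)} for e in script.events])


def read_script_jsonl(path) -> ScenarioScript:
    records = _load_lines(path)
    header = records[0]
    events = [ScriptEvent(time=r["time"], zone=r["zone"], dwell=r["dwell"])
              for r in records[1:]]
    return ScenarioScript(name=header["name"], events=events,
                          total_duration=header["total_duration"],
                          time_compression=header["time_compression"],
                          sleep_window=tuple(header["sleep_window"]))


def write_trajectory_jsonl(path, traj: Trajectory) -> None:
    header = {"kind": "trajectory", "seed": traj.seed,
              "walker_weight_kg": traj.walker_weight_kg,
              "meta": traj.meta}
    _dump_lines(path, [header] + [
        {"kind": "footstep", **asdict(fs)} for fs in traj.footsteps])


def read_trajectory_jsonl(path) -> Trajectory:
    records = _load_lines(path)
    header = records[0]
    steps = [Footstep(time=r["time"], address=r["address"],
                      quadrant=r["quadrant"], pressure=r["pressure"])
             for r in records[1:]]
    return Trajectory(footsteps=steps, seed=header["seed"],
                      walker_weight_kg=header["walker_weight_kg"],
                      meta=header.get("meta", {}))


def write_activations_jsonl(path, stream: ActivationStream) -> None:
    _dump_lines(path, [asdict(e) for e in stream.events])


def write_trace_jsonl(path, trace: PositionTrace) -> None:
    _dump_lines(path, [asdict(s) for s in trace.samples])


def write_zone_trace_jsonl(path, samples: Sequence[ZoneSample]) -> None:
    _dump_lines(path, [asdict(s) for s in samples])


def read_zone_trace_jsonl(path) -> list[ZoneSample]:
    return [ZoneSample(time=r["time"], address=r["address"],
                       quadrant=r["quadrant"], zone=r["zone"])
            for r in _load_lines(path)]


def write_report(json_path, txt_path, report: BehaviorReport) -> None:
    payload = {
        "sleep_periods": [list(p) for p in report.sleep_periods],
        "wakeup_count": report.wakeup_count,
        "toilet_visits_total": report.toilet_visits_total,
        "toilet_visits_during_sleep": report.toilet_visits_during_sleep,
        "dwell_minutes": report.dwell_minutes,
        "zone_entries": report.zone_entries,
        "matching_accuracy": report.matching_accuracy,
    }
    Path(json_path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    lines = [
        f"sleep_periods = {len(report.sleep_periods)}",
        f"wakeup_count = {report.wakeup_count}",
        f"toilet_visits_total = {report.toilet_visits_total}",
        f"toilet_visits_during_sleep = {report.toilet_visits_during_sleep}",
    ]
    for zone, minutes in sorted(report.dwell_minutes.items()):
        lines.append(f"dwell_minutes.{zone} = {minutes:.1f}")
    for zone, n in sorted(report.zone_entries.items()):
        lines.append(f"zone_entries.{zone} = {n}")
    if report.matching_accuracy is not None:
        lines.append(f"matching_accuracy = {report.matching_accuracy:.1f}")
    Path(txt_path).write_text("\n".join(lines) + "\n")
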