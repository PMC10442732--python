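"""Behavior metrics from zone traces: sleep, wake-ups, toilet visits, dwell.

A zone trace is first collapsed into maximal *episodes*: runs of samples in
the same zone with inter-sample gaps below a debounce window.  An episode
counts as a *visit* only if it is at least a minimum dwell long AND contains
a stay point — sustained presence on a single mat.  The stay-point rule is
what separates genuine visits from walking transits that merely clip a
zone: a walker advances one mat per step and never accumulates single-mat
dwell, whereas someone actually staying in a zone stands (shifting weight)
on one mat for minutes.  On top of the episodes the module computes the
scenario metrics — sleep periods (sustained bedroom presence inside the
sleep window), nocturnal wake-ups (bedroom exit with return, both inside
the window), toilet visits (total and with onset inside the window), and
per-zone dwell minutes — and scores recognized per-zone entry counts
against a script's embedded ground truth as a matching-accuracy percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .scenarios import SLEEP_WINDOW, ZONES
from .tracking import DEFAULT_DEBOUNCE_MINUTES, ZoneSample

__all__ = [
    "AnalysisParams",
    "BehaviorReport",
    "Episode",
    "analyze",
    "comparison_table",
    "count_toilet_visits",
    "count_wakeups",
    "detect_sleep_periods",
    "episodes_from_trace",
    "match_accuracy",
    "zone_entry_counts",
    "zone_time_summary",
]

#: minimum episode dwell (simulated minutes) to count a visit; debounced,
#: prevents single-sample flickers from counting
MIN_VISIT_MINUTES = 1.0
#: minimum continuous single-mat dwell that marks a stay point; a walker at
#: the default gait (one mat per 0.5 simulated minutes) accumulates none,
#: while the shortest scripted stay (5 min at one anchor mat) far exceeds it
MIN_STAY_MINUTES = 2.0
MIN_SLEEP_MINUTES = 60.0
MOVEMENT_TOLERANCE_MINUTES = 5.0


@dataclass(frozen=True)
class AnalysisParams:
    debounce: float = DEFAULT_DEBOUNCE_MINUTES
    min_visit_minutes: float = MIN_VISIT_MINUTES
    min_stay_minutes: float = MIN_STAY_MINUTES
    min_sleep_minutes: float = MIN_SLEEP_MINUTES
    movement_tolerance: float = MOVEMENT_TOLERANCE_MINUTES
    sleep_window: tuple[float, float] = SLEEP_WINDOW


@dataclass(frozen=True)
class Episode:
    zone: Optional[str]
    start: float
    end: float
    n_samples: int
    stay_minutes: float = 0.0  # longest continuous single-mat dwell

    @property
    def dwell(self) -> float:
        return self.end - self.start


@dataclass
class BehaviorReport:
    sleep_periods: list[tuple[float, float]]
    wakeup_count: int
    toilet_visits_total: int
    toilet_visits_during_sleep: int
    dwell_minutes: dict[str, float]
    zone_entries: dict[str, int]
    matching_accuracy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.wakeup_count < 0 or self.toilet_visits_total < 0:
            raise ValueError("counts must be >= 0")
        if self.toilet_visits_during_sleep > self.toilet_visits_total:
            raise ValueError("during-sleep visits cannot exceed the total")


def episodes_from_trace(samples: Sequence[ZoneSample],
                        debounce: float = DEFAULT_DEBOUNCE_MINUTES
                        ) -> list[Episode]:
    """Collapse a zone-labeled trace into maximal same-zone episodes.

    A new episode starts when the zone changes or the time gap since the
    previous sample exceeds the debounce window.  Each episode records its
    longest continuous single-mat dwell (``stay_minutes``).
    """
    episodes: list[Episode] = []
    run_addr, run_start, prev = None, 0.0, None
    for s in samples:
        new_episode = not (episodes and episodes[-1].zone == s.zone
                           and s.time - episodes[-1].end <= debounce)
        if new_episode:
            episodes.append(Episode(zone=s.zone, start=s.time, end=s.time,
                                    n_samples=1))
            run_addr, run_start = s.address, s.time
        else:
            last = episodes[-1]
            if s.address != run_addr or s.time - prev.time > debounce:
                run_addr, run_start = s.address, s.time
            episodes[-1] = Episode(
                zone=last.zone, start=last.start, end=s.time,
                n_samples=last.n_samples + 1,
                stay_minutes=max(last.stay_minutes, s.time - run_start))
        prev = s
    return episodes


def _visits(episodes: Sequence[Episode], zone: str, min_minutes: float,
            min_stay: float = 0.0) -> list[Episode]:
    return [e for e in episodes if e.zone == zone and e.dwell >= min_minutes
            and e.stay_minutes >= min_stay]


def detect_sleep_periods(samples: Sequence[ZoneSample],
                         params: AnalysisParams = AnalysisParams()
                         ) -> list[tuple[float, float]]:
    """Sustained bedroom presence inside the sleep window.

    Bedroom episodes are clipped to the window, merged across interruptions
    shorter than the movement tolerance, and kept when at least the minimum
    sleep dwell long.
    """
    lo, hi = params.sleep_window
    eps = episodes_from_trace(samples, params.debounce)
    clipped = []
    for e in _visits(eps, "bedroom", 0.0, params.min_stay_minutes):
        start, end = max(e.start, lo), min(e.end, hi)
        if end > start:
            clipped.append((start, end))
    merged: list[list[float]] = []
    for start, end in clipped:
        if merged and start - merged[-1][1] < params.movement_tolerance:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e - s >= params.min_sleep_minutes]


def count_wakeups(samples: Sequence[ZoneSample],
                  params: AnalysisParams = AnalysisParams()) -> int:
    """Nocturnal bedroom exits with a subsequent return.

    Counts consecutive bedroom visit pairs whose gap (exit .. re-entry)
    lies inside the sleep window.
    """
    lo, hi = params.sleep_window
    eps = episodes_from_trace(samples, params.debounce)
    bedroom = _visits(eps, "bedroom", params.min_visit_minutes,
                      params.min_stay_minutes)
    count = 0
    for prev_e, next_e in zip(bedroom, bedroom[1:]):
        if lo <= prev_e.end < hi and lo <= next_e.start < hi:
            count += 1
    return count


def count_toilet_visits(samples: Sequence[ZoneSample],
                        params: AnalysisParams = AnalysisParams()
                        ) -> tuple[int, int]:
    """(total, during-sleep) toilet visit episodes; onset decides nocturnal."""
    lo, hi = params.sleep_window
    eps = episodes_from_trace(samples, params.debounce)
    visits = _visits(eps, "toilet", params.min_visit_minutes,
                     params.min_stay_minutes)
    during = sum(1 for e in visits if lo <= e.start < hi)
    return len(visits), during


def zone_time_summary(samples: Sequence[ZoneSample],
                      debounce: float = DEFAULT_DEBOUNCE_MINUTES
                      ) -> dict[str, float]:
    """Per-zone summed dwell minutes over all episodes."""
    out = {z: 0.0 for z in ZONES}
    for e in episodes_from_trace(samples, debounce):
        if e.zone in out:
            out[e.zone] += e.dwell
    return out


def zone_entry_counts(samples: Sequence[ZoneSample],
                      params: AnalysisParams = AnalysisParams()
                      ) -> dict[str, int]:
    """Recognized number of visit episodes per zone (transits filtered)."""
    eps = episodes_from_trace(samples, params.debounce)
    return {z: len(_visits(eps, z, params.min_visit_minutes,
                           params.min_stay_minutes)) for z in ZONES}


def analyze(samples: Sequence[ZoneSample],
            params: AnalysisParams = AnalysisParams()) -> BehaviorReport:
    """Full behavior report for one zone trace (accuracy left unscored)."""
    total, during = count_toilet_visits(samples, params)
    return BehaviorReport(
        sleep_periods=detect_sleep_periods(samples, params),
        wakeup_count=count_wakeups(samples, params),
        toilet_visits_total=total,
        toilet_visits_during_sleep=during,
        dwell_minutes=zone_time_summary(samples, params.debounce),
        zone_entries=zone_entry_counts(samples, params),
    )


def match_accuracy(report: BehaviorReport, truth: dict) -> float:
    """Percent of per-zone entry counts recognized exactly.

    ``truth`` is a script ground-truth dict (or its ``zone_entries``
    sub-dict); 100 iff every compared count matches.
    """
    truth_entries = truth.get("zone_entries", truth)
    if not truth_entries:
        raise ValueError("empty ground truth")
    matched = sum(1 for z, n in truth_entries.items()
                  if report.zone_entries.get(z, 0) == n)
    return matched / len(truth_entries) * 100.0


def comparison_table(report: BehaviorReport, truth: dict) -> pd.DataFrame:
    """Detected-vs-truth per-zone entry counts (one row per zone)."""
    truth_entries = truth.get("zone_entries", truth)
    rows = []
    for z in ZONES:
        t = truth_entries.get(z)
        d = report.zone_entries.get(z, 0)
        rows.append({"zone": z, "truth_entries": t, "detected_entries": d,
                     "match": bool(t == d)})
    return pd.DataFrame(rows)
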