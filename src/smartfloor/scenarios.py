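"""Synthetic occupant simulator: rooms, scenario scripts, trajectories.

This module is the package's data generator.  It emulates the desk-scale
study conditions: a connected room of 500x500 mm mats (fixture: 57 mats,
41.3 m^2 of floor) partitioned into bedroom / toilet / entrance / activity
zones; a 24-hour day compressed 60x (1 real second = 1 simulated minute, so
the whole day runs in 24 real minutes); and three scripted behavior
scenarios:

* ``normal`` — one uninterrupted night of sleep, a handful of daytime
  toilet visits;
* ``sleep_disorder`` — the same day but the sleeper leaves the bedroom 3
  times during the night and returns;
* ``urinary_frequency`` — 8 toilet visits over the day, exactly 2 of them
  during the sleep window.

The simulated day starts at 20:00, so the 23:00-07:00 sleep window is the
contiguous interval [180, 660) simulated minutes.  A single 55 kg occupant
walks at 2 steps per real second (one footstep per 0.5 simulated minutes)
and is always somewhere on the floor: between scripted visits they stand at
a fixed per-zone anchor mat shifting their weight, and they depart just in
time to arrive at the next scripted zone on schedule.  Footstep peak
pressures stay within the sensor's 0-0.12 kg/cm^2 range.  Every quantity of
randomness (step pressures, quadrants, timing jitter) flows from one seed;
episode counts are seed-invariant by construction, so the scripted ground
truth is recoverable from any seeded trajectory.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .mapping import SpatialMap, run_auto_mapping
from .network import GridLayout, LayoutError, build_network, step

__all__ = [
    "DAY_MINUTES",
    "GaitParams",
    "RoomMap",
    "ScenarioScript",
    "ScriptEvent",
    "SLEEP_WINDOW",
    "TIME_COMPRESSION",
    "Footstep",
    "Trajectory",
    "ZONES",
    "generate_layout",
    "generate_trajectory",
    "make_room",
    "plan_path",
    "scenario_names",
    "script_scenario",
]

ZONES = ("bedroom", "toilet", "entrance", "activity")
DEFAULT_ZONE_FRACTIONS = {"bedroom": 0.35, "toilet": 0.10,
                          "entrance": 0.10, "activity": 0.45}

DAY_MINUTES = 1440.0          # simulated minutes per scenario
TIME_COMPRESSION = 60         # 1 real second = 1 simulated minute
DAY_START_CLOCK = "20:00"     # wall-clock time of simulated minute 0
SLEEP_WINDOW = (180.0, 660.0)  # 23:00 .. 07:00 in simulated minutes

FIXTURE_N_MATS = 57
FIXTURE_AREA_M2 = 41.3        # room area at the 57-mat fixture scale
WALKER_WEIGHT_KG = 55.0
SENSOR_FULL_SCALE = 0.12      # kg/cm^2


@dataclass(frozen=True)
class GaitParams:
    """Walking/standing parameters of the simulated occupant.

    Times are simulated minutes (divide by 60 for real seconds).  The step
    interval of 0.5 corresponds to a 2 steps/s cadence in real time.
    """

    step_interval: float = 0.5         # min between footsteps while walking
    stationary_interval: float = 0.5   # min between weight shifts while standing
    time_jitter: float = 0.05          # max +/- jitter on walking step times
    step_pressure_mean: float = 0.060  # kg/cm^2, walking peak pressure
    step_pressure_sd: float = 0.012
    stationary_pressure_mean: float = 0.045
    stationary_pressure_sd: float = 0.004
    pressure_floor: float = 0.035      # keep every event above detection floor


@dataclass
class RoomMap:
    """A mapped room: layout, auto-mapped addresses, and zone assignment."""

    layout: GridLayout
    spatial_map: SpatialMap
    zones: dict[str, set[int]]
    area_m2: float

    def __post_init__(self) -> None:
        addresses = set(self.spatial_map.entries)
        for name, members in self.zones.items():
            if name not in ZONES:
                raise ValueError(f"unknown zone {name!r}")
            if not members:
                raise ValueError(f"zone {name!r} is empty")
            if not members <= addresses:
                raise ValueError(f"zone {name!r} references unmapped addresses")
        all_members = [a for m in self.zones.values() for a in m]
        if len(all_members) != len(set(all_members)):
            raise ValueError("zones must be disjoint")
        self._zone_of = {a: z for z, m in self.zones.items() for a in m}
        self._graph = None
        self._anchors: dict[str, int] = {}

    def zone_of(self, address: int) -> Optional[str]:
        return self._zone_of.get(address)

    def adjacency(self) -> nx.Graph:
        """Mat adjacency graph on addresses (4-connected grid cells)."""
        if self._graph is None:
            g = nx.Graph()
            coord = {a: self.spatial_map.coord_of(a) for a in self.spatial_map.entries}
            by_cell = {c: a for a, c in coord.items()}
            g.add_nodes_from(coord)
            for a, c in coord.items():
                for d in ("N", "E", "S", "W"):
                    nb = by_cell.get(step(c, d))
                    if nb is not None:
                        g.add_edge(a, nb)
            self._graph = g
        return self._graph

    def anchor(self, zone: str) -> int:
        """Deterministic dwell mat for a zone: the member closest (graph
        distance) to the gateway mat, ties broken by (row, col)."""
        if zone not in self._anchors:
            dist = nx.single_source_shortest_path_length(self.adjacency(), 1)
            self._anchors[zone] = min(
                self.zones[zone],
                key=lambda a: (dist.get(a, 1 << 30), self.spatial_map.coord_of(a)))
        return self._anchors[zone]

    def zone_table(self) -> pd.DataFrame:
        rows = [{"address": a, "zone": z}
                for z in ZONES for a in sorted(self.zones.get(z, ()))]
        return pd.DataFrame(rows)


def generate_layout(n_mats: int, seed: int = 0,
                    rotations_random: bool = True) -> GridLayout:
    """Random connected grid layout (polyomino growth from the origin cell).

    The first cell hosts the gateway mat.  Deterministic under the seed.
    """
    if n_mats < 1:
        raise LayoutError("need at least one mat")
    rng = np.random.default_rng(seed)
    deltas = [(-1, 0), (0, 1), (1, 0), (0, -1)]
    cells = [(0, 0)]
    occupied = {(0, 0)}
    while len(cells) < n_mats:
        base = cells[int(rng.integers(len(cells)))]
        dr, dc = deltas[int(rng.integers(4))]
        cand = (base[0] + dr, base[1] + dc)
        if cand not in occupied:
            occupied.add(cand)
            cells.append(cand)
    r_off = -min(r for r, _ in cells)
    c_off = -min(c for _, c in cells)
    placements = {}
    for i, (r, c) in enumerate(cells):
        rot = int(rng.choice((0, 90, 180, 270))) if rotations_random else 0
        placements[f"mat-{i + 1:03d}"] = (r + r_off, c + c_off, rot)
    return GridLayout(placements=placements, gateway_id="mat-001")


def _partition_zones(spatial: SpatialMap, fractions: dict[str, float],
                     rng: np.random.Generator) -> dict[str, set[int]]:
    """Partition mapped addresses into 4 spatially coherent zones.

    Seeds are spread by greedy farthest-point sampling; zones then grow
    breadth-first, always expanding the zone furthest below its target
    share, so fractions are respected approximately and every zone is
    connected.
    """
    addrs = sorted(spatial.entries)
    coord = {a: spatial.coord_of(a) for a in addrs}
    by_cell = {c: a for a, c in coord.items()}
    neighbors = {a: sorted(
        by_cell[step(coord[a], d)] for d in ("N", "E", "S", "W")
        if step(coord[a], d) in by_cell) for a in addrs}

    n = len(addrs)
    targets = {z: max(1, round(fractions[z] * n)) for z in ZONES}
    # adjust rounding so targets sum to n (shave/grow the largest zone)
    largest = max(ZONES, key=lambda z: targets[z])
    targets[largest] += n - sum(targets.values())

    def bfs_dist(src: int) -> dict[int, int]:
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in neighbors[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        return dist

    seeds = [int(rng.choice(addrs))]
    while len(seeds) < 4:
        dists = [bfs_dist(s) for s in seeds]
        best = max((a for a in addrs if a not in seeds),
                   key=lambda a: (min(d.get(a, 0) for d in dists), -a))
        seeds.append(best)

    assigned: dict[int, str] = {}
    frontiers: dict[str, deque[int]] = {}
    counts = {z: 0 for z in ZONES}
    for z, s in zip(ZONES, seeds):
        assigned[s] = z
        frontiers[z] = deque([s])
        counts[z] = 1

    def can_grow(z: str) -> bool:
        return any(any(v not in assigned for v in neighbors[u])
                   for u in frontiers[z])

    while len(assigned) < n:
        open_zones = [z for z in ZONES if can_grow(z)]
        under = [z for z in open_zones if counts[z] < targets[z]]
        pool = under or open_zones
        z = min(pool, key=lambda z: (counts[z] / targets[z], ZONES.index(z)))
        grown = False
        while frontiers[z] and not grown:
            u = frontiers[z][0]
            free = [v for v in neighbors[u] if v not in assigned]
            if not free:
                frontiers[z].popleft()
                continue
            v = free[0]
            assigned[v] = z
            counts[z] += 1
            frontiers[z].append(v)
            grown = True

    zones: dict[str, set[int]] = {z: set() for z in ZONES}
    for a, z in assigned.items():
        zones[z].add(a)
    return zones


def make_room(n_mats: int = FIXTURE_N_MATS,
              zone_fractions: Optional[dict[str, float]] = None,
              seed: int = 0) -> RoomMap:
    """Generate a connected room, auto-map it, and carve it into 4 zones.

    The floor area scales with the fixture density (41.3 m^2 at 57 mats).
    Deterministic under the seed; needs at least one mat per zone.
    """
    if n_mats < 4:
        raise LayoutError("need at least 4 mats (one per zone)")
    fractions = dict(DEFAULT_ZONE_FRACTIONS)
    if zone_fractions:
        fractions.update(zone_fractions)
    rng = np.random.default_rng(seed)
    layout = generate_layout(n_mats, seed=int(rng.integers(1 << 31)))
    network = build_network(layout)
    spatial = run_auto_mapping(network)
    zones = _partition_zones(spatial, fractions, rng)
    area = round(n_mats * FIXTURE_AREA_M2 / FIXTURE_N_MATS, 1)
    return RoomMap(layout=layout, spatial_map=spatial, zones=zones, area_m2=area)


@dataclass(frozen=True)
class ScriptEvent:
    """One scripted visit: be in ``zone`` from ``time`` for at least
    ``dwell`` simulated minutes."""

    time: float
    zone: str
    dwell: float


@dataclass
class ScenarioScript:
    """Ordered scenario timetable with embedded ground truth."""

    name: str
    events: list[ScriptEvent]
    total_duration: float = DAY_MINUTES
    time_compression: int = TIME_COMPRESSION
    sleep_window: tuple[float, float] = SLEEP_WINDOW

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if times != sorted(times):
            raise ValueError("script events must be time-ordered")
        for e in self.events:
            if not 0.0 <= e.time < self.total_duration:
                raise ValueError(f"event at {e.time} outside the day")
            if e.zone not in ZONES:
                raise ValueError(f"unknown zone {e.zone!r}")

    def truth(self) -> dict:
        """Ground-truth counts implied by the timetable.

        A wake-up is a single non-bedroom visit bracketed by bedroom visits
        with both the exit and the return inside the sleep window.  A sleep
        period is a bedroom stay overlapping the window by >= 60 minutes.
        """
        lo, hi = self.sleep_window
        zone_entries = {z: 0 for z in ZONES}
        for e in self.events:
            zone_entries[e.zone] += 1
        wakeups = 0
        for i in range(1, len(self.events) - 1):
            prev_e, e, next_e = self.events[i - 1], self.events[i], self.events[i + 1]
            if (e.zone != "bedroom" and prev_e.zone == "bedroom"
                    and next_e.zone == "bedroom"
                    and lo <= e.time < hi and lo <= next_e.time < hi):
                wakeups += 1
        toilet = [e for e in self.events if e.zone == "toilet"]
        toilet_during_sleep = sum(1 for e in toilet if lo <= e.time < hi)
        sleep_periods = 0
        for i, e in enumerate(self.events):
            if e.zone != "bedroom":
                continue
            end = (self.events[i + 1].time if i + 1 < len(self.events)
                   else self.total_duration)
            overlap = min(end, hi) - max(e.time, lo)
            if overlap >= 60.0:
                sleep_periods += 1
        return {
            "zone_entries": zone_entries,
            "wakeup_count": wakeups,
            "toilet_visits_total": len(toilet),
            "toilet_visits_during_sleep": toilet_during_sleep,
            "sleep_period_count": sleep_periods,
        }


def _normal_events() -> list[ScriptEvent]:
    return [ScriptEvent(t, z, d) for t, z, d in [
        (0, "entrance", 8), (20, "activity", 55), (90, "toilet", 5),
        (110, "activity", 45), (170, "bedroom", 480), (670, "toilet", 5),
        (690, "activity", 110), (815, "toilet", 5), (835, "activity", 120),
        (970, "entrance", 5), (990, "activity", 170), (1175, "toilet", 5),
        (1195, "activity", 110), (1320, "bedroom", 110),
    ]]


def _sleep_disorder_events() -> list[ScriptEvent]:
    ev = [ScriptEvent(t, z, d) for t, z, d in [
        (0, "entrance", 8), (20, "activity", 55), (90, "toilet", 5),
        (110, "activity", 45),
        (170, "bedroom", 85),
        (270, "activity", 6),   # wake-up 1
        (290, "bedroom", 90),
        (395, "activity", 6),   # wake-up 2
        (415, "bedroom", 100),
        (530, "activity", 6),   # wake-up 3
        (550, "bedroom", 100),
        (670, "toilet", 5), (690, "activity", 110), (815, "toilet", 5),
        (835, "activity", 120), (970, "entrance", 5), (990, "activity", 170),
        (1175, "toilet", 5), (1195, "activity", 110), (1320, "bedroom", 110),
    ]]
    return ev


def _urinary_frequency_events() -> list[ScriptEvent]:
    return [ScriptEvent(t, z, d) for t, z, d in [
        (0, "entrance", 8), (20, "activity", 50), (85, "toilet", 5),
        (105, "activity", 45),
        (170, "bedroom", 110),
        (295, "toilet", 5),     # nocturnal visit 1
        (315, "bedroom", 150),
        (480, "toilet", 5),     # nocturnal visit 2
        (500, "bedroom", 145),
        (670, "toilet", 5), (690, "activity", 90), (795, "toilet", 5),
        (815, "activity", 90), (920, "toilet", 5), (940, "activity", 100),
        (1055, "toilet", 5), (1075, "activity", 80), (1170, "toilet", 5),
        (1190, "activity", 105), (1320, "bedroom", 110),
    ]]


_SCENARIOS = {
    "normal": _normal_events,
    "sleep_disorder": _sleep_disorder_events,
    "urinary_frequency": _urinary_frequency_events,
}


def scenario_names() -> tuple[str, ...]:
    return tuple(_SCENARIOS)


def script_scenario(name: str) -> ScenarioScript:
    """Fixed 24-hour timetable for one of the three scenarios."""
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(_SCENARIOS)}")
    script = ScenarioScript(name=name, events=_SCENARIOS[name]())
    truth = script.truth()
    if name == "sleep_disorder":
        assert truth["wakeup_count"] == 3
    if name == "urinary_frequency":
        assert truth["toilet_visits_total"] == 8
        assert truth["toilet_visits_during_sleep"] == 2
    if name == "normal":
        assert truth["wakeup_count"] == 0 and truth["toilet_visits_total"] < 8
    return script


def plan_path(room: RoomMap, from_addr: int, to_addr: int) -> list[int]:
    """Shortest mat path over room adjacency, deterministic.

    Ties break lexicographically by the sequence of (row, col) coordinates
    along the path (Dijkstra on (length, coordinate-key)).
    """
    g = room.adjacency()
    if from_addr not in g or to_addr not in g:
        raise KeyError("both endpoints must be room mats")
    coord = {a: room.spatial_map.coord_of(a) for a in g}
    best: dict[int, tuple] = {from_addr: (0, (coord[from_addr],))}
    heap = [(0, (coord[from_addr],), from_addr)]
    while heap:
        dist, key, u = heapq.heappop(heap)
        if (dist, key) > best.get(u, (1 << 30, ())):
            continue
        if u == to_addr:
            break
        for v in sorted(g[u], key=lambda a: coord[a]):
            cand = (dist + 1, key + (coord[v],))
            if cand < best.get(v, (1 << 30, ())):
                best[v] = cand
                heapq.heappush(heap, (*cand, v))
    if to_addr not in best:
        raise ValueError(f"no path between {from_addr} and {to_addr}")
    by_cell = {coord[a]: a for a in g}
    return [by_cell[c] for c in best[to_addr][1]]


@dataclass(frozen=True)
class Footstep:
    """One pressure event: a footstep or stationary weight shift."""

    time: float        # simulated minutes
    address: int
    quadrant: int      # 0..3
    pressure: float    # peak, kg/cm^2


@dataclass
class Trajectory:
    """Seeded footstep stream for one scenario run."""

    footsteps: list[Footstep]
    seed: int
    walker_weight_kg: float = WALKER_WEIGHT_KG
    meta: dict = field(default_factory=dict)


def generate_trajectory(script: ScenarioScript, room: RoomMap,
                        gait: GaitParams = GaitParams(),
                        seed: int = 0) -> Trajectory:
    """Realize a scenario script as a footstep stream in a room.

    The occupant stands at the current zone's anchor mat, emitting a weight
    shift every ``stationary_interval`` minutes, and departs at
    ``next_event.time - walk_duration`` so each scripted visit begins on
    schedule.  Walking follows the deterministic shortest anchor-to-anchor
    path, one footstep per mat.  Only pressures, quadrants and small step
    jitters vary with the seed; visit structure does not.
    """
    if not script.events:
        return Trajectory(footsteps=[], seed=seed, meta={"stay_minutes": {}})
    for e in script.events:
        if not room.zones.get(e.zone):
            raise ValueError(f"zone {e.zone!r} has no mats")
    rng = np.random.default_rng(seed)
    anchors = {z: room.anchor(z) for z in ZONES}
    g = gait
    steps: list[Footstep] = []
    stay_minutes: dict[str, float] = {z: 0.0 for z in ZONES}

    def clip_pressure(x: float) -> float:
        return float(min(max(x, g.pressure_floor), SENSOR_FULL_SCALE))

    def emit(time: float, address: int, mean: float, sd: float) -> None:
        steps.append(Footstep(
            time=round(time, 4), address=address,
            quadrant=int(rng.integers(4)),
            pressure=clip_pressure(rng.normal(mean, sd))))

    events = script.events
    arrival = events[0].time
    here = anchors[events[0].zone]
    for i, ev in enumerate(events):
        if i + 1 < len(events):
            nxt = events[i + 1]
            path = plan_path(room, here, anchors[nxt.zone])
            walk = (len(path) - 1) * g.step_interval
            depart = nxt.time - walk
        else:
            path, depart = [here], script.total_duration - g.stationary_interval
        depart = max(depart, arrival + g.stationary_interval)
        # stationary weight shifts at the anchor
        t = arrival
        while t < depart:
            emit(t, here, g.stationary_pressure_mean, g.stationary_pressure_sd)
            t += g.stationary_interval
        stay_minutes[ev.zone] += depart - arrival
        # walk to the next anchor
        if i + 1 < len(events):
            for k, address in enumerate(path[1:], start=1):
                jitter = float(rng.uniform(-g.time_jitter, g.time_jitter))
                emit(depart + k * g.step_interval + jitter, address,
                     g.step_pressure_mean, g.step_pressure_sd)
            arrival = events[i + 1].time
            here = anchors[events[i + 1].zone]

    steps.sort(key=lambda s: s.time)
    return Trajectory(footsteps=steps, seed=seed,
                      meta={"scenario": script.name,
                            "stay_minutes": stay_minutes,
                            "anchors": anchors})
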