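"""Data model of the mat grid and the broadcast bus.

Each 500x500 mm mat unit carries four sensing quadrants (one electrode plate
per quadrant), four neighbor-probe ports labeled in the mat's LOCAL frame
(N, E, S, W), a bus endpoint, and an installation rotation restricted to
quarter turns.  Mats placed on adjacent grid cells are physically linked
through the pair of ports that face each other, honoring each mat's rotation.
The bus is a lossless, totally ordered broadcast log: every frame is visible
to the gateway and to all mats in sequence order (the deployed system uses a
CAN multimaster bus; arbitration and timing are irrelevant to the discovery
logic and are not modeled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

__all__ = [
    "Bus",
    "BusFrame",
    "DIRECTIONS",
    "GridLayout",
    "LayoutError",
    "MatUnit",
    "Network",
    "QUADRANTS",
    "build_network",
    "global_to_local",
    "layout_from_csv",
    "layout_to_csv",
    "local_to_global",
    "opposite",
    "step",
]

#: global / local compass directions, clockwise order
DIRECTIONS = ("N", "E", "S", "W")
#: quadrant (electrode plate) labels in the mat's local frame, index 0-3
QUADRANTS = ("NW", "NE", "SW", "SE")
ROTATIONS = (0, 90, 180, 270)

#: (d_row, d_col) for one grid step in each global direction
#: rows increase southward, columns increase eastward
_DELTA = {"N": (-1, 0), "E": (0, 1), "S": (1, 0), "W": (0, -1)}

MAT_SIZE_MM = 500
PLATE_SIZE_MM = 220  # Results text also quotes 210 mm; field is overridable


class LayoutError(ValueError):
    """Raised for inconsistent grid layouts."""


def opposite(direction: str) -> str:
    return DIRECTIONS[(DIRECTIONS.index(direction) + 2) % 4]


def step(coord: tuple[int, int], direction: str) -> tuple[int, int]:
    """Grid coordinate one step away in a global direction."""
    dr, dc = _DELTA[direction]
    return (coord[0] + dr, coord[1] + dc)


def _check_rotation(rotation: int) -> None:
    if rotation not in ROTATIONS:
        raise LayoutError(f"rotation must be one of {ROTATIONS}, got {rotation}")


def local_to_global(rotation: int, local_port: str) -> str:
    """Global direction faced by a local port on a mat rotated clockwise by
    ``rotation`` degrees.  Rotation 0 is the identity; the map is a bijection
    for every rotation."""
    _check_rotation(rotation)
    if local_port not in DIRECTIONS:
        raise ValueError(f"unknown port {local_port!r}")
    return DIRECTIONS[(DIRECTIONS.index(local_port) + rotation // 90) % 4]


def global_to_local(rotation: int, direction: str) -> str:
    """Local port of a mat rotated by ``rotation`` that faces the given
    global direction (inverse of :func:`local_to_global`)."""
    _check_rotation(rotation)
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    return DIRECTIONS[(DIRECTIONS.index(direction) - rotation // 90) % 4]


@dataclass
class MatUnit:
    """One smart floor mat: 4 quadrant sensors, 4 probe ports, a rotation,
    and a bus endpoint.  ``address`` is unassigned until discovery."""

    hardware_id: str
    rotation: int = 0
    address: Optional[int] = None
    quadrants: tuple[str, ...] = QUADRANTS
    ports: tuple[str, ...] = DIRECTIONS

    def __post_init__(self) -> None:
        _check_rotation(self.rotation)
        if len(self.quadrants) != 4 or len(self.ports) != 4:
            raise LayoutError("a mat has exactly 4 quadrants and 4 ports")


@dataclass
class GridLayout:
    """Physical placement of mats: hardware id -> (row, col, rotation).

    Exactly one mat is flagged as gateway-attached.  Adjacency is 4-connected
    (|d_row| + |d_col| = 1).
    """

    placements: dict[str, tuple[int, int, int]]
    gateway_id: str
    mat_size_mm: int = MAT_SIZE_MM
    plate_size_mm: int = PLATE_SIZE_MM

    def __post_init__(self) -> None:
        if not self.placements:
            raise LayoutError("layout must contain at least one mat")
        if self.gateway_id not in self.placements:
            raise LayoutError(f"gateway mat {self.gateway_id!r} not in layout")
        seen: dict[tuple[int, int], str] = {}
        for hw, (row, col, rot) in self.placements.items():
            _check_rotation(rot)
            if row < 0 or col < 0:
                raise LayoutError(f"negative coordinate for {hw!r}: {(row, col)}")
            if (row, col) in seen:
                raise LayoutError(
                    f"mats {seen[(row, col)]!r} and {hw!r} share cell {(row, col)}")
            seen[(row, col)] = hw

    def coord_of(self, hardware_id: str) -> tuple[int, int]:
        row, col, _ = self.placements[hardware_id]
        return (row, col)

    def rotation_of(self, hardware_id: str) -> int:
        return self.placements[hardware_id][2]

    def __len__(self) -> int:
        return len(self.placements)


@dataclass(frozen=True)
class BusFrame:
    """One frame on the broadcast bus."""

    sender: str  # hardware id or "gateway"
    kind: str    # probe_command | port_report | address_assign | sensor_reading
    payload: tuple
    sequence: int = -1  # assigned by the bus on exchange

    KINDS = ("probe_command", "port_report", "address_assign", "sensor_reading")


@dataclass
class Bus:
    """Lossless totally ordered broadcast log."""

    log: list[BusFrame] = field(default_factory=list)
    _next_seq: int = 1

    def append(self, frame: BusFrame) -> BusFrame:
        stamped = BusFrame(sender=frame.sender, kind=frame.kind,
                           payload=frame.payload, sequence=self._next_seq)
        self._next_seq += 1
        self.log.append(stamped)
        return stamped


@dataclass
class Network:
    """Built network: mats, physical port links, and the shared bus.

    ``port_links`` maps (hardware_id, local_port) -> (hardware_id, local_port)
    for every physically mated port pair; boundary ports are absent.
    """

    layout: GridLayout
    mats: dict[str, MatUnit]
    port_links: dict[tuple[str, str], tuple[str, str]]
    bus: Bus = field(default_factory=Bus)

    @property
    def gateway_id(self) -> str:
        return self.layout.gateway_id

    def graph(self) -> nx.Graph:
        """Mat-level adjacency graph (one edge per linked port pair)."""
        g = nx.Graph()
        g.add_nodes_from(self.mats)
        for (a, _), (b, _) in self.port_links.items():
            g.add_edge(a, b)
        return g

    def n_links(self) -> int:
        return len(self.port_links) // 2

    def exchange(self, frame: BusFrame) -> BusFrame:
        """Broadcast a frame: appended to the global ordered log, visible to
        the gateway and every mat."""
        if frame.sender != "gateway" and frame.sender not in self.mats:
            raise KeyError(f"unknown sender {frame.sender!r}")
        if frame.kind not in BusFrame.KINDS:
            raise ValueError(f"unknown frame kind {frame.kind!r}")
        return self.bus.append(frame)


def build_network(layout: GridLayout) -> Network:
    """Materialize mats and physical port links from a grid layout.

    Facing ports of 4-adjacent mats are linked, honoring each mat's
    rotation: mat A's local port that faces global direction d mates with
    the neighbor's local port that faces the opposite direction.
    """
    mats = {hw: MatUnit(hardware_id=hw, rotation=rot)
            for hw, (_, _, rot) in layout.placements.items()}
    by_coord = {layout.coord_of(hw): hw for hw in layout.placements}
    links: dict[tuple[str, str], tuple[str, str]] = {}
    for hw, (row, col, rot) in layout.placements.items():
        for direction in DIRECTIONS:
            nb_coord = step((row, col), direction)
            nb = by_coord.get(nb_coord)
            if nb is None:
                continue
            port_a = global_to_local(rot, direction)
            port_b = global_to_local(layout.rotation_of(nb), opposite(direction))
            links[(hw, port_a)] = (nb, port_b)
    return Network(layout=layout, mats=mats, port_links=links)


def layout_to_csv(layout: GridLayout, path) -> None:
    rows = [
        {"hardware_id": hw, "row": r, "col": c, "rotation": rot,
         "gateway": int(hw == layout.gateway_id)}
        for hw, (r, c, rot) in sorted(layout.placements.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def layout_from_csv(path) -> GridLayout:
    df = pd.read_csv(path)
    required = {"hardware_id", "row", "col", "rotation", "gateway"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"layout file missing columns: {sorted(missing)}")
    gateways = df.loc[df["gateway"].astype(int) == 1, "hardware_id"].tolist()
    if len(gateways) != 1:
        raise LayoutError(f"layout must flag exactly one gateway mat, found {len(gateways)}")
    placements = {
        str(rec.hardware_id): (int(rec.row), int(rec.col), int(rec.rotation))
        for rec in df.itertuples()
    }
    return GridLayout(placements=placements, gateway_id=str(gateways[0]))
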