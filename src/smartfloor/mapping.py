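"""Gateway-driven auto-mapping: discovery of mat count, position, rotation.

The gateway addresses mats one at a time.  An addressed mat switches its
four probe ports to output and drives them low sequentially (local N, E, S,
W); all unaddressed mats hold their ports in input state, and the one
neighbor whose port sees the low signal reports its receiving local port
number on the bus.  From the prober's known grid pose the gateway infers the
neighbor's grid cell (one step in the probe's global direction) and its
rotation (the unique quarter turn under which the reported local port faces
back toward the prober).  Newly reported mats are assigned the next address
and queued; the frontier expands breadth-first until every mat reachable
from the gateway mat has a map entry.

Coordinates are relative to the gateway mat, which is the origin; its
rotation is taken as reported through the gateway connector.  Addresses are
sequential integers in discovery order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .network import (DIRECTIONS, BusFrame, Network, global_to_local,
                      local_to_global, opposite, step)

__all__ = [
    "MapEntry",
    "MapInconsistencyError",
    "SpatialMap",
    "infer_orientation",
    "probe_port",
    "run_auto_mapping",
]


class MapInconsistencyError(RuntimeError):
    """Two discovery paths place a mat at contradictory poses."""


@dataclass(frozen=True)
class MapEntry:
    hardware_id: str
    row: int
    col: int
    rotation: int


@dataclass
class SpatialMap:
    """Output of auto-mapping: address -> pose, in discovery order.

    Addresses are unique and contiguous from 1.  ``residual`` lists mats
    that are physically present but unreachable from the gateway mat.
    """

    entries: dict[int, MapEntry] = field(default_factory=dict)
    discovery_order: list[int] = field(default_factory=list)
    residual: list[str] = field(default_factory=list)

    @property
    def total_mats(self) -> int:
        return len(self.entries)

    def address_of(self, hardware_id: str) -> int:
        for addr, entry in self.entries.items():
            if entry.hardware_id == hardware_id:
                return addr
        raise KeyError(hardware_id)

    def coord_of(self, address: int) -> tuple[int, int]:
        e = self.entries[address]
        return (e.row, e.col)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"address": addr, "hardware_id": e.hardware_id, "row": e.row,
              "col": e.col, "rotation": e.rotation}
             for addr, e in sorted(self.entries.items())]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def render_ascii(self) -> str:
        """Human-readable grid rendering: each cell shows address/rotation."""
        if not self.entries:
            return "(empty map)\n"
        rows = [e.row for e in self.entries.values()]
        cols = [e.col for e in self.entries.values()]
        r0, r1 = min(rows), max(rows)
        c0, c1 = min(cols), max(cols)
        by_cell = {(e.row, e.col): addr for addr, e in self.entries.items()}
        rot_of = {(e.row, e.col): e.rotation for e in self.entries.values()}
        width = max(len(f"{a}r{rot_of[c]}") for c, a in by_cell.items()) + 1
        out = io.StringIO()
        for r in range(r0, r1 + 1):
            cells = []
            for c in range(c0, c1 + 1):
                addr = by_cell.get((r, c))
                cells.append("." .center(width) if addr is None
                             else f"{addr}r{rot_of[(r, c)]}".center(width))
            out.write("".join(cells).rstrip() + "\n")
        return out.getvalue()


def probe_port(network: Network, address: int, local_port: str) -> list[BusFrame]:
    """Drive one probe line of the addressed mat low.

    Returns the port_report frames emitted on the bus: exactly one if a
    neighbor is mated on that port (payload = the neighbor's receiving local
    port index in its own frame), empty for a boundary port.
    """
    prober = next((m for m in network.mats.values() if m.address == address), None)
    if prober is None:
        raise KeyError(f"no mat holds address {address}")
    network.exchange(BusFrame(sender="gateway", kind="probe_command",
                              payload=(address, DIRECTIONS.index(local_port))))
    link = network.port_links.get((prober.hardware_id, local_port))
    if link is None:
        return []
    neighbor_id, neighbor_port = link
    report = network.exchange(BusFrame(
        sender=neighbor_id, kind="port_report",
        payload=(DIRECTIONS.index(neighbor_port),)))
    return [report]


def infer_orientation(probe_global_direction: str, reported_local_port: str) -> int:
    """Rotation of a newly found mat from one probe observation.

    The neighbor's reported local port physically faces back toward the
    prober, i.e. the global direction opposite the probe direction; exactly
    one quarter turn achieves that.
    """
    want = opposite(probe_global_direction)
    rotation = 90 * ((DIRECTIONS.index(want)
                      - DIRECTIONS.index(reported_local_port)) % 4)
    assert local_to_global(rotation, reported_local_port) == want
    return rotation


def run_auto_mapping(network: Network) -> SpatialMap:
    """Run the discovery protocol from the gateway mat.

    Breadth-first frontier expansion with the fixed local probe order
    N, E, S, W gives a deterministic discovery order.  A mat reachable by
    several paths is cross-checked; contradictory poses raise
    :class:`MapInconsistencyError`.  Unreachable mats are returned in the
    ``residual`` list, never silently dropped.
    """
    for mat in network.mats.values():
        mat.address = None

    gw_id = network.gateway_id
    gw_mat = network.mats[gw_id]
    gw_mat.address = 1
    network.exchange(BusFrame(sender="gateway", kind="address_assign",
                              payload=(1,)))
    spatial = SpatialMap()
    spatial.entries[1] = MapEntry(hardware_id=gw_id, row=0, col=0,
                                  rotation=gw_mat.rotation)
    spatial.discovery_order.append(1)
    next_address = 2
    queue = [1]
    while queue:
        address = queue.pop(0)
        entry = spatial.entries[address]
        for local_port in DIRECTIONS:  # fixed probe order N, E, S, W
            reports = probe_port(network, address, local_port)
            if not reports:
                continue
            reporter_id = reports[0].sender
            reported_port = DIRECTIONS[reports[0].payload[0]]
            probe_dir = local_to_global(entry.rotation, local_port)
            cell = step((entry.row, entry.col), probe_dir)
            rotation = infer_orientation(probe_dir, reported_port)
            reporter = network.mats[reporter_id]
            if reporter.address is not None:
                known = spatial.entries[reporter.address]
                if (known.row, known.col) != cell or known.rotation != rotation:
                    raise MapInconsistencyError(
                        f"mat {reporter_id!r} placed at {cell} rot {rotation} "
                        f"but previously at {(known.row, known.col)} rot "
                        f"{known.rotation}")
                continue
            reporter.address = next_address
            network.exchange(BusFrame(sender="gateway", kind="address_assign",
                                      payload=(next_address,)))
            spatial.entries[next_address] = MapEntry(
                hardware_id=reporter_id, row=cell[0], col=cell[1],
                rotation=rotation)
            spatial.discovery_order.append(next_address)
            queue.append(next_address)
            next_address += 1

    discovered = {e.hardware_id for e in spatial.entries.values()}
    spatial.residual = sorted(set(network.mats) - discovered)
    return spatial
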