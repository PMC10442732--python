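import pytest
from hypothesis import HealthCheck, settings

import smartfloor as sf
from smartfloor.network import GridLayout
from smartfloor.scenarios import RoomMap

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def curve():
    return sf.calibrate_response()


@pytest.fixture(scope="session")
def divider():
    return sf.DividerConfig()


@pytest.fixture(scope="session")
def fixture_room():
    """The standard 57-mat test room (seed 1)."""
    return sf.make_room(57, seed=1)


def line_layout(n, rotations=None, gateway="mat-001"):
    """A 1xN row of mats, gateway on the west end."""
    rotations = rotations or [0] * n
    placements = {f"mat-{i + 1:03d}": (0, i, rotations[i]) for i in range(n)}
    return GridLayout(placements=placements, gateway_id=gateway)


def square_layout(rotations=None):
    """A 2x2 block of mats, gateway at the NW corner."""
    rotations = rotations or [0] * 4
    coords = [(0, 0), (0, 1), (1, 0), (1, 1)]
    placements = {f"mat-{i + 1:03d}": (*coords[i], rotations[i])
                  for i in range(4)}
    return GridLayout(placements=placements, gateway_id="mat-001")


def room_from_layout(layout, zones):
    """RoomMap over an explicit layout and a zone -> addresses mapping."""
    spatial = sf.run_auto_mapping(sf.build_network(layout))
    return RoomMap(layout=layout, spatial_map=spatial, zones=zones,
                   area_m2=len(layout) * 41.3 / 57)


@pytest.fixture()
def line_room():
    """1x4 row, one mat per zone: entrance(1) activity(2) toilet(3) bedroom(4)."""
    return room_from_layout(line_layout(4), {
        "entrance": {1}, "activity": {2}, "toilet": {3}, "bedroom": {4}})
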