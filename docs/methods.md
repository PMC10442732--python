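# Methods

This note documents the models behind `smartfloor`, the parameters that
matter, the synthetic-data generator's scope, and the numerical and design
choices made where the design was genuinely open.

## Sensor model

**Response curve.** The piezo-resistive textile is characterized by two
printed endpoints — 4.1 kΩ unloaded, 0.25 kΩ at the 0.12 kg/cm² full scale —
with no published functional form in between. We interpolate with a
normalized exponential pinned exactly to both endpoints,

    R(P) = R_full + (R_zero − R_full) · (e^(−kP/P_full) − e^(−k)) / (1 − e^(−k)),

chosen because it is monotone, strictly positive, two-point calibrated, and
has one curvature parameter `k` (`shape_param`). The default
`k = ln(R_zero/R_full)` makes the curve the pure exponential
`R_zero·e^(−kP/P_full)`, the simplest monotone law consistent with the
endpoints. Percolating nanotube networks are often closer to exponential
than linear in this regime, but the choice is a modeling convenience, not a
fitted microstructure claim.

**Hysteresis.** The unloading branch is the loading branch contracted
toward `R_full` by `hysteresis_width ∈ [0, 1)`:
`R_un = R_full + (1 − h)(R_load − R_full)`. The loop closes at full scale
and is widest at zero load; the unloading branch never exceeds the loading
branch and stays strictly decreasing and positive for any `h`. The loop's
exact shape is otherwise unconstrained by the characterization data, so
the simplest one-parameter family is used. The degree of hysteresis is
computed from any measured loop as
`DH = (A_loading − A_unloading)/A_loading × 100` with trapezoidal areas
over a common pressure span; it is 0 for coincident branches and invariant
to uniform rescaling of the response values.

**Drift.** Baseline resistance decays with press count n as
`scale(n) = a + (1 − a)·e^(−n/τ)` with asymptote fraction `a = 0.80`
(a 20 % terminal decrease). The time constant is fixed by requiring the
scale to first come within 1 % (relative) of the asymptote at the observed
saturation point of ≈8000 presses: `τ = 8000/ln((1 − a)/(0.01·a)) ≈ 2485`.
Drift multiplies the whole curve, so monotonicity in pressure is preserved
at any wear state.

**Repeatability.** Measurement noise is relative Gaussian:
`R_i = R̄(1 + ε)`, `ε ~ N(0, σ²)`. σ is calibrated so the probability of a
reading falling within ±10 % of the mean equals the observed 92 %
repeatability: `σ = 0.10 / z_0.96 ≈ 0.0571`. The accuracy statistic itself
is distribution-free (a band-coverage count) and is checked against brute
force enumeration.

**Divider and threshold.** The sensor sits on the high side with the load
resistor to ground, so output voltage rises with pressure. Over the
calibrated range at 5 V the swing `|V(R_min) − V(R_max)|` is maximized by
the 1 kΩ standard value; the continuum optimum is the geometric mean
`√(R_min·R_max) ≈ 1012 Ω` (stationarity of `R/(R+R_min) − R/(R+R_max)`).
The characterization supply is 5 V; the deployed system's 6 V supply is
kept in the configuration for the network model. The default activation
threshold is the midpoint between the unloaded readout (≈0.98 V) and the
readout under a typical 0.05 kg/cm² footstep (≈2.20 V), which digitizes
every pressure above ≈0.028 kg/cm² as active.

## Mat network and auto-mapping

Mats are unit cells on a 4-connected grid; each has four probe ports
labeled in its **local** frame and an installation rotation in
{0°, 90°, 180°, 270°} clockwise. `local_to_global(rot, port)` rotates the
port label; facing ports of adjacent mats are physically linked. The bus is
a lossless, totally ordered broadcast log — the deployed hardware uses CAN,
whose arbitration and timing do not affect discovery correctness and are
not modeled.

Discovery is breadth-first from the gateway mat with the fixed local probe
order N, E, S, W, which makes the discovery order (and hence address
assignment) fully deterministic. The neighbor that sees a probe reports its
receiving local port; since that port physically faces back toward the
prober, the neighbor's rotation is the unique quarter turn mapping the
reported port onto the opposite of the probe's global direction, and its
cell is the prober's cell displaced one step. Mats reachable by several
paths are cross-checked on every re-observation; a contradiction raises a
map-inconsistency error rather than silently overwriting. The map is
expressed relative to the gateway mat (origin, rotation as reported through
its connector); unreachable mats are returned in a residual list.
Addresses are sequential in discovery order and deliberately decoupled from
coordinates, since no authoritative row/column numbering formula is
available.

## Synthetic occupant generator

**What it emulates.** A single 55 kg occupant in a connected room of
500×500 mm mats (fixture: 57 mats, area scaled as 41.3 m² at that size),
partitioned into bedroom / toilet / entrance / activity zones; a 24-hour
day compressed 60× (1 real second = 1 simulated minute); footstep peak
pressures within the sensor's 0–0.12 kg/cm² range; cadence 2 steps per
real second, i.e. one footstep per 0.5 simulated minutes.

**Rooms.** Layouts are random connected polyominoes grown from the origin;
zones are carved by farthest-point seeding plus balanced breadth-first
growth toward target fractions (bedroom 0.35, toilet 0.10, entrance 0.10,
activity 0.45), giving four disjoint connected regions. Everything is
deterministic under the seed.

**Scenarios.** The simulated day starts at 20:00, so the 23:00–07:00 sleep
window is the contiguous interval [180, 660) simulated minutes. The
baseline timetable is necessarily arbitrary (any realistic day would do);
it is fixed, documented in `scenarios.py`, and shared by all three
scenarios: the sleep-disorder variant inserts 3 nocturnal
bedroom→activity→bedroom excursions, and the urinary-frequency variant has
8 toilet visits of which exactly 2 start inside the sleep window (those two
also count as wake-ups, since a bedroom exit-and-return brackets them; the
wake-up and toilet counters are otherwise independent). Each script embeds
its ground truth (per-zone entry counts, wake-ups, toilet totals, sleep
periods) computed from its own timetable.

**Trajectories.** Each zone has a fixed anchor mat (the member nearest the
gateway, ties by coordinate) where the occupant stands, shifting weight
every 0.5 minutes. The occupant is on the floor continuously: they depart
the current anchor exactly `path_length × 0.5 min` before the next scripted
visit time and walk the deterministic shortest path, so every visit begins
on schedule and no silent gaps exist between presence segments. Seeds vary
pressures, quadrants, and per-step timing jitter (±0.05 min) only — anchor
choice, paths, and therefore episode structure are seed-invariant, which is
what makes the 100 % matching-accuracy property reproducible across seeds.
Realized per-zone stay minutes (which exceed the scripted minimum dwells
because the occupant waits at the anchor until departure) are recorded in
the trajectory metadata and used by the dwell-consistency tests.

**What it does not emulate.** No biomechanical gait (no double-support
pressure profiles, no partial footfalls across mat edges — each footstep
loads exactly one quadrant, as if snapped to a plate center), no multiple
occupants, no sensor crosstalk, and the room partition has no corridors or
walls: walks legitimately cut through foreign zones. Passing tests
therefore demonstrate the pipeline's internal correctness under these
idealized conditions, not robustness to real gait variability or multi-person
confusion.

## Tracking and behavior analysis

Activations above threshold become position samples; simultaneous
activations (double support) resolve to the latest onset, the natural tie
break for forward gait. Samples collapse into zone episodes with a 2-minute
debounce (bridging the 0.5-minute inter-step gaps). An episode counts as a
**visit** only if (a) it lasts at least 1 minute and (b) it contains a
**stay point** — at least 2 minutes of continuous presence on a single mat.
The stay-point rule is the standard stop-versus-pass-through discriminator
in indoor mobility analysis, and it is what makes visit counting robust to
room geometry: a walker advances one mat per step and accumulates no
single-mat dwell no matter how many mats of a foreign zone the shortest
path clips, while a genuine visit always parks on one mat for minutes.
Episode length alone cannot make this distinction at a 60× time
compression, where crossing three mats already takes one simulated minute.

Sleep periods are bedroom episodes clipped to the sleep window, merged
across interruptions shorter than a 5-minute movement tolerance, and kept
at ≥60 minutes. A wake-up is a consecutive pair of bedroom visits whose
exit and re-entry both lie inside the window. Toilet visits are counted by
episode, with the onset deciding whether a visit is nocturnal. Matching
accuracy is the percentage of per-zone entry counts recognized exactly
against the script's ground truth.

### Key defaults

| parameter | default | unit | why |
|---|---|---|---|
| R_zero / R_full | 4100 / 250 | Ω | printed calibration endpoints |
| P_full | 0.12 | kg/cm² | sensor full scale |
| shape_param | ln(R_zero/R_full) ≈ 2.80 | — | pure-exponential interpolation |
| divider supply / load | 5 / 1000 | V / Ω | characterization supply; swing-optimal load |
| drift asymptote / saturation | 0.80 / 8000 | — / presses | 20 % terminal decrease by ≈8000 presses |
| noise spread | 0.0571 | — | 92 % coverage of the ±10 % band |
| step interval | 0.5 | sim min | 2 steps/s real under 60× compression |
| debounce | 2 | sim min | bridges inter-step gaps, splits real absences |
| min visit / min stay | 1 / 2 | sim min | flicker floor / stop-vs-transit discriminator |
| min sleep dwell / movement tolerance | 60 / 5 | sim min | sustained sleep; brief stirring does not split |
| sleep window | [180, 660) | sim min | 23:00–07:00 with the day starting 20:00 |

## Numerical choices and degenerate inputs

Out-of-range pressures clamp to [0, P_full] by default and raise in strict
mode. `optimal_load` breaks ties toward the smallest resistance. DH
requires matching pressure spans (relative tolerance 1e−9) and a nonzero
loading area. The drift saturation scan uses a 1e−9 relative epsilon so the
designed exact crossing at 8000 presses is not lost to floating-point
rounding. Path planning is Dijkstra on (length, coordinate-sequence) keys,
making shortest-path tie-breaks lexicographic and platform-independent.
JSON writers sort keys and rely on repr-round-trip floats, so equal seeds
give byte-identical output files.

## Problem sizes

The standard fixture is the 57-mat room; the mapping property suite runs
200 random connected layouts of 1–80 mats with random rotations; the
scenario property suite runs all three scenarios at 50 trajectory seeds in
the fixture room; the repeatability statistic uses 10 000 draws. These
sizes exercise every code path at full fidelity while keeping a complete
run of suite plus reproduction script comfortably interactive.

## Known limitations

Single occupant; no probabilistic filtering (tracking is direct
signal-to-mat matching, as in the modeled system); no hot-plug re-mapping
or multi-gateway support; the electrode-plate dead zones between the four
plates of a mat are represented only by snapping footsteps to one quadrant;
plate size is 220 mm by default although 210 mm also appears in the
hardware description (overridable field); and the behavior metrics are
descriptive, not diagnostic — no clinical interpretation is attempted.
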