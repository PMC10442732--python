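"""Electrical model of the piezo-resistive sensing textile.

The sensing element is a carbon-nanotube-coated polyester fabric whose
resistance falls monotonically as pressure is applied: compression packs the
conductive network more densely, conductivity rises, resistance drops.  The
module models

* the calibrated pressure -> resistance response (two-point exponential
  interpolation through the zero-load and full-scale endpoints),
* loading/unloading hysteresis and its area-based summary statistic
  (degree of hysteresis, DH),
* slow baseline drift over repeated presses (saturating exponential),
* measurement repeatability (a relative-noise model and the fraction of
  repeated readings inside a +/-band around the mean),
* the voltage-divider readout and its load-resistor design problem, and
* thresholding of the divider output into a binary activation level.

Default calibration follows the characterized textile: 4.1 kOhm unloaded
falling to 0.25 kOhm at 0.12 kg/cm^2, read out at a 5 V characterization
supply (the deployed system runs the mats from 6 V).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "CalibrationError",
    "DividerConfig",
    "DriftModel",
    "NoiseModel",
    "ResponseCurve",
    "accuracy_statistic",
    "calibrate_noise",
    "calibrate_response",
    "default_threshold",
    "degree_of_hysteresis",
    "digitize",
    "divider_voltage",
    "drift_scale",
    "drift_saturation_press",
    "export_curve_csv",
    "optimal_load",
    "resistance_at",
]

# Printed characterization values for the textile.
DEFAULT_R_ZERO = 4100.0       # ohm, unloaded
DEFAULT_R_FULL = 250.0        # ohm, at full-scale pressure
DEFAULT_P_FULL = 0.12         # kg/cm^2, full-scale pressure
CHARACTERIZATION_SUPPLY = 5.0  # V, bench supply used for the divider curves
SYSTEM_SUPPLY = 6.0            # V, supply of the deployed mat system
DEFAULT_R_LOAD = 1000.0        # ohm, load resistor chosen for maximum swing
TYPICAL_STEP_PRESSURE = 0.05   # kg/cm^2, repeatability test weight

#: standard E-series candidates evaluated for the load-resistor choice, ohm
STANDARD_LOAD_CANDIDATES = (100.0, 220.0, 470.0, 1000.0, 2200.0, 4700.0, 10000.0)


class CalibrationError(ValueError):
    """Raised for physically inconsistent sensor parameters."""


@dataclass(frozen=True)
class DriftModel:
    """Saturating baseline drift of the textile under repeated presses.

    The baseline resistance decays toward ``asymptote_fraction`` of its
    initial value as the nanotube network rearranges, with the scale factor
    first coming within 1% (relative) of the asymptote at
    ``saturation_presses``.
    """

    asymptote_fraction: float = 0.80
    saturation_presses: int = 8000

    def __post_init__(self) -> None:
        if not 0.0 < self.asymptote_fraction <= 1.0:
            raise CalibrationError(
                f"asymptote_fraction must be in (0, 1], got {self.asymptote_fraction}"
            )
        if self.saturation_presses <= 0:
            raise CalibrationError("saturation_presses must be positive")

    @property
    def tau(self) -> float:
        """Press-count time constant of the exponential decay."""
        a = self.asymptote_fraction
        if a == 1.0:
            return float("inf")
        return self.saturation_presses / math.log((1.0 - a) / (0.01 * a))


def drift_scale(model: DriftModel, n_presses) -> float | np.ndarray:
    """Multiplicative resistance scale factor after ``n_presses`` presses.

    scale(0) = 1, non-increasing, bounded below by the asymptote fraction.
    """
    n = np.asarray(n_presses, dtype=float)
    if np.any(n < 0):
        raise ValueError("press count must be >= 0")
    a = model.asymptote_fraction
    if a == 1.0:
        out = np.ones_like(n)
    else:
        out = a + (1.0 - a) * np.exp(-n / model.tau)
    return float(out) if np.isscalar(n_presses) else out


def drift_saturation_press(model: DriftModel, max_presses: int = 50_000,
                           rel_tol: float = 0.01) -> int:
    """First press count at which the drift scale is within ``rel_tol``
    (relative) of the asymptote, scanning integer counts up to ``max_presses``."""
    n = np.arange(max_presses + 1)
    scale = drift_scale(model, n)
    # small epsilon so the designed exact crossing is not missed to rounding
    within = scale - model.asymptote_fraction <= rel_tol * model.asymptote_fraction * (1 + 1e-9)
    idx = np.flatnonzero(within)
    if idx.size == 0:
        raise ValueError(f"drift does not saturate within {max_presses} presses")
    return int(idx[0])


@dataclass(frozen=True)
class ResponseCurve:
    """Calibrated monotone pressure -> resistance model with hysteresis.

    The loading branch is a normalized exponential pinned exactly to the two
    calibration endpoints::

        R(P) = R_full + (R_zero - R_full) * (e^{-k P/P_full} - e^{-k}) / (1 - e^{-k})

    with curvature ``shape_param = k``.  For the default
    ``k = ln(R_zero/R_full)`` this reduces to the pure exponential
    ``R_zero * exp(-k P / P_full)``.  The unloading branch is the loading
    branch contracted toward ``R_full`` by ``hysteresis_width`` (the loop
    closes at full scale and is widest at zero load); it therefore never
    exceeds the loading branch and stays strictly decreasing and positive.
    ``drift_state`` counts accumulated presses; the drift model rescales the
    whole curve, preserving monotonicity.
    """

    r_zero: float
    r_full: float
    p_full: float
    shape_param: float
    hysteresis_width: float = 0.0
    drift_state: int = 0
    drift: DriftModel = field(default_factory=DriftModel)

    def __post_init__(self) -> None:
        if not (self.r_zero > self.r_full > 0.0):
            raise CalibrationError(
                f"need R_zero > R_full > 0, got {self.r_zero}, {self.r_full}"
            )
        if self.p_full <= 0.0:
            raise CalibrationError("full-scale pressure must be positive")
        if self.shape_param <= 0.0:
            raise CalibrationError("shape_param must be positive")
        if not 0.0 <= self.hysteresis_width < 1.0:
            raise CalibrationError("hysteresis_width must be in [0, 1)")
        if self.drift_state < 0:
            raise CalibrationError("drift_state must be >= 0")

    def resistance(self, pressure, branch: str = "loading",
                   clamp: bool = True) -> float | np.ndarray:
        """Resistance (ohm) at ``pressure`` (kg/cm^2) on the given branch.

        Out-of-range pressures are clamped to [0, P_full] by default; with
        ``clamp=False`` they raise instead (strict mode).
        """
        if branch not in ("loading", "unloading"):
            raise ValueError(f"unknown branch {branch!r}")
        p = np.asarray(pressure, dtype=float)
        if clamp:
            p = np.clip(p, 0.0, self.p_full)
        elif np.any((p < 0.0) | (p > self.p_full)):
            raise ValueError("pressure outside [0, P_full] in strict mode")
        k = self.shape_param
        decay = (np.exp(-k * p / self.p_full) - math.exp(-k)) / (1.0 - math.exp(-k))
        r = self.r_full + (self.r_zero - self.r_full) * decay
        if branch == "unloading" and self.hysteresis_width > 0.0:
            r = self.r_full + (1.0 - self.hysteresis_width) * (r - self.r_full)
        if self.drift_state > 0:
            r = r * drift_scale(self.drift, self.drift_state)
        return float(r) if np.isscalar(pressure) else r

    def pressed(self, n_presses: int) -> "ResponseCurve":
        """Curve after ``n_presses`` additional presses of drift wear."""
        if n_presses < 0:
            raise ValueError("press count must be >= 0")
        return replace(self, drift_state=self.drift_state + int(n_presses))


def calibrate_response(r_zero: float = DEFAULT_R_ZERO,
                       r_full: float = DEFAULT_R_FULL,
                       p_full: float = DEFAULT_P_FULL,
                       shape_param: float | None = None,
                       hysteresis_width: float = 0.0) -> ResponseCurve:
    """Two-point calibration of the response curve.

    The returned curve passes exactly through ``(0, r_zero)`` and
    ``(p_full, r_full)`` and is strictly decreasing in between.  When
    ``shape_param`` is omitted it defaults to ``ln(r_zero / r_full)``,
    the pure-exponential interpolation.
    """
    if not (r_zero > r_full > 0.0):
        raise CalibrationError(f"need R_zero > R_full > 0, got {r_zero}, {r_full}")
    if p_full <= 0.0:
        raise CalibrationError("full-scale pressure must be positive")
    if shape_param is None:
        shape_param = math.log(r_zero / r_full)
    return ResponseCurve(r_zero=r_zero, r_full=r_full, p_full=p_full,
                         shape_param=shape_param,
                         hysteresis_width=hysteresis_width)


def resistance_at(curve: ResponseCurve, pressure, branch: str = "loading",
                  clamp: bool = True):
    """Functional alias for :meth:`ResponseCurve.resistance`."""
    return curve.resistance(pressure, branch=branch, clamp=clamp)


@dataclass(frozen=True)
class DividerConfig:
    """Voltage-divider readout: sensor on the high side, load resistor to
    ground, so the output voltage rises as pressure lowers the sensor
    resistance."""

    v_supply: float = CHARACTERIZATION_SUPPLY
    r_load: float = DEFAULT_R_LOAD

    def __post_init__(self) -> None:
        if self.v_supply <= 0.0:
            raise CalibrationError("supply voltage must be positive")
        if self.r_load <= 0.0:
            raise CalibrationError("load resistance must be positive")


def divider_voltage(r_sensor, cfg: DividerConfig):
    """Divider output V_out = V_supply * R_load / (R_load + R_sensor)."""
    r = np.asarray(r_sensor, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("sensor resistance must be positive")
    out = cfg.v_supply * cfg.r_load / (cfg.r_load + r)
    return float(out) if np.isscalar(r_sensor) else out


def optimal_load(candidates: Iterable[float],
                 r_range: tuple[float, float],
                 v_supply: float = CHARACTERIZATION_SUPPLY) -> float:
    """Load resistor maximizing the output-voltage swing across the sensor's
    resistance range.

    The swing is ``|V(R_min) - V(R_max)|``; ties break toward the smallest
    resistance.  (The continuum optimum is the geometric mean
    ``sqrt(R_min * R_max)``.)
    """
    cands = sorted(float(c) for c in candidates)
    if not cands:
        raise ValueError("candidate list must be non-empty")
    r_min, r_max = r_range
    if not (0.0 < r_min < r_max):
        raise ValueError(f"resistance range must be ordered and positive, got {r_range}")
    best, best_swing = None, -1.0
    for c in cands:
        cfg = DividerConfig(v_supply=v_supply, r_load=c)
        swing = abs(divider_voltage(r_min, cfg) - divider_voltage(r_max, cfg))
        if swing > best_swing:
            best, best_swing = c, swing
    return best


def degree_of_hysteresis(loading: Sequence[tuple[float, float]],
                         unloading: Sequence[tuple[float, float]],
                         span_rtol: float = 1e-9) -> float:
    """Degree of hysteresis, percent.

    DH = (A_loading - A_unloading) / A_loading * 100, with areas under the
    pressure-response branches computed by trapezoidal integration over a
    common pressure span.  Zero for coincident branches.
    """
    load = np.asarray(loading, dtype=float)
    unload = np.asarray(unloading, dtype=float)
    if load.ndim != 2 or unload.ndim != 2 or load.shape[0] < 2 or unload.shape[0] < 2:
        raise ValueError("each branch needs >= 2 (pressure, value) points")
    load = load[np.argsort(load[:, 0])]
    unload = unload[np.argsort(unload[:, 0])]
    span = max(abs(load[-1, 0] - load[0, 0]), 1.0)
    if (abs(load[0, 0] - unload[0, 0]) > span_rtol * span
            or abs(load[-1, 0] - unload[-1, 0]) > span_rtol * span):
        raise ValueError("loading and unloading branches must span the same "
                         "pressure interval")
    a_load = float(np.trapezoid(load[:, 1], load[:, 0]))
    a_unload = float(np.trapezoid(unload[:, 1], unload[:, 0]))
    if a_load == 0.0:
        raise ValueError("zero loading area: DH undefined")
    return (a_load - a_unload) / a_load * 100.0


@dataclass(frozen=True)
class NoiseModel:
    """Relative (multiplicative) Gaussian measurement noise on resistance."""

    relative_spread: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_spread < 0.0:
            raise CalibrationError("relative_spread must be >= 0")

    def draw(self, center: float, n: int) -> np.ndarray:
        """``n`` noisy readings around ``center`` ohm."""
        rng = np.random.default_rng(self.seed)
        return center * (1.0 + rng.normal(0.0, self.relative_spread, size=n))


def calibrate_noise(band: float = 0.10, coverage: float = 0.92,
                    seed: int = 0) -> NoiseModel:
    """Noise model whose +/-``band`` coverage around the mean equals
    ``coverage`` (Gaussian quantile calibration)."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    spread = band / norm.ppf(0.5 + coverage / 2.0)
    return NoiseModel(relative_spread=spread, seed=seed)


def accuracy_statistic(samples: Sequence[float], band: float = 0.10) -> float:
    """Repeatability statistic: percent of samples within ``mean*(1 +/- band)``."""
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    if band < 0.0:
        raise ValueError("band must be >= 0")
    mean = x.mean()
    lo, hi = mean * (1.0 - band), mean * (1.0 + band)
    return float(np.mean((x >= lo) & (x <= hi)) * 100.0)


def digitize(voltage: float, threshold: float) -> tuple[int, float]:
    """Threshold the analog divider output into an activation level.

    Returns ``(level, voltage)``: level 1 iff ``voltage >= threshold``; the
    analog value is retained for magnitude traces.
    """
    return (1 if voltage >= threshold else 0, voltage)


def default_threshold(curve: ResponseCurve, cfg: DividerConfig,
                      typical_pressure: float = TYPICAL_STEP_PRESSURE) -> float:
    """Activation threshold: midpoint between the unloaded readout and the
    readout under a typical footstep pressure."""
    v_idle = divider_voltage(curve.resistance(0.0), cfg)
    v_step = divider_voltage(curve.resistance(typical_pressure), cfg)
    return 0.5 * (v_idle + v_step)


def curve_table(curve: ResponseCurve, cfg: DividerConfig,
                n_points: int = 49) -> pd.DataFrame:
    """Tabulate both branches and the divider output over [0, P_full]."""
    p = np.linspace(0.0, curve.p_full, n_points)
    r_load_branch = curve.resistance(p, branch="loading")
    r_unload_branch = curve.resistance(p, branch="unloading")
    return pd.DataFrame({
        "pressure_kg_cm2": p,
        "r_loading_ohm": r_load_branch,
        "r_unloading_ohm": r_unload_branch,
        "v_out_loading": divider_voltage(r_load_branch, cfg),
    })


def export_curve_csv(path, curve: ResponseCurve, cfg: DividerConfig,
                     n_points: int = 49) -> None:
    curve_table(curve, cfg, n_points).to_csv(path, index=False)


# -- plain-text key/value sensor configuration --------------------------------

_CONFIG_KEYS = ("r_zero_ohm", "r_full_ohm", "p_full_kg_cm2", "shape_param",
                "hysteresis_width", "v_supply", "r_load_ohm", "threshold_v")


def read_sensor_config(path) -> dict[str, float]:
    """Parse a ``key = value`` sensor-parameter file; '#' starts a comment."""
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in _CONFIG_KEYS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = float(val.strip())
    return values


def sensor_from_config(values: dict[str, float]) -> tuple[ResponseCurve, DividerConfig, float]:
    """Build (curve, divider, threshold) from a config dict, with defaults."""
    curve = calibrate_response(
        r_zero=values.get("r_zero_ohm", DEFAULT_R_ZERO),
        r_full=values.get("r_full_ohm", DEFAULT_R_FULL),
        p_full=values.get("p_full_kg_cm2", DEFAULT_P_FULL),
        shape_param=values.get("shape_param"),
        hysteresis_width=values.get("hysteresis_width", 0.0),
    )
    cfg = DividerConfig(v_supply=values.get("v_supply", CHARACTERIZATION_SUPPLY),
                        r_load=values.get("r_load_ohm", DEFAULT_R_LOAD))
    threshold = values.get("threshold_v", default_threshold(curve, cfg))
    return curve, cfg, threshold
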