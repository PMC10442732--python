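"""Sensor model: response curve, divider, hysteresis, drift, repeatability."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import smartfloor as sf
from smartfloor.sensor import (DriftModel, NoiseModel, calibrate_noise,
                               curve_table, default_threshold,
                               drift_saturation_press, read_sensor_config,
                               sensor_from_config)


class TestResponseCurve:
    def test_calibration_endpoints_are_exact(self, curve):
        assert curve.resistance(0.0) == pytest.approx(4100.0)
        assert curve.resistance(0.12) == pytest.approx(250.0)

    def test_pure_exponential_closed_form(self):
        # R_full = R_zero/e over unit pressure: R(0.5) = R_zero * e^-0.5
        c = sf.calibrate_response(1000.0, 1000.0 / math.e, 1.0, shape_param=1.0)
        assert c.resistance(0.5) == pytest.approx(1000.0 * math.exp(-0.5))

    @pytest.mark.parametrize("branch", ["loading", "unloading"])
    def test_strictly_decreasing_on_both_branches(self, branch):
        c = sf.calibrate_response(hysteresis_width=0.15)
        p = np.linspace(0.0, 0.12, 200)
        r = c.resistance(p, branch=branch)
        assert np.all(np.diff(r) < 0)
        assert np.all(r > 0)

    def test_hysteresis_branch_ordering(self):
        c = sf.calibrate_response(hysteresis_width=0.1)
        p = 0.06
        assert c.resistance(p, "loading") > c.resistance(p, "unloading")
        c0 = sf.calibrate_response(hysteresis_width=0.0)
        assert c0.resistance(p, "loading") == c0.resistance(p, "unloading")

    def test_out_of_range_clamps_or_errors(self, curve):
        assert curve.resistance(1.0) == pytest.approx(250.0)
        assert curve.resistance(-0.5) == pytest.approx(4100.0)
        with pytest.raises(ValueError):
            curve.resistance(1.0, clamp=False)

    @pytest.mark.parametrize("r_zero,r_full", [(250.0, 4100.0), (-5.0, -10.0),
                                               (100.0, 100.0)])
    def test_inverted_or_nonpositive_resistances_rejected(self, r_zero, r_full):
        with pytest.raises(sf.CalibrationError):
            sf.calibrate_response(r_zero, r_full, 0.12)

    def test_drift_composition_preserves_monotonicity(self, curve):
        worn = curve.pressed(20_000)
        p = np.linspace(0.0, 0.12, 100)
        assert np.all(np.diff(worn.resistance(p)) < 0)
        assert worn.resistance(0.0) < curve.resistance(0.0)


class TestDivider:
    @pytest.mark.parametrize("r_sensor,r_load,v,expected", [
        (1000.0, 1000.0, 5.0, 2.5),      # equal-leg divider
        (250.0, 1000.0, 5.0, 4.0),       # loaded sensor
        (1e9, 1000.0, 5.0, 0.0),         # unloaded limit
    ])
    def test_divider_arithmetic(self, r_sensor, r_load, v, expected):
        cfg = sf.DividerConfig(v_supply=v, r_load=r_load)
        assert sf.divider_voltage(r_sensor, cfg) == pytest.approx(expected, abs=1e-5)

    def test_nonpositive_resistance_rejected(self, divider):
        with pytest.raises(ValueError):
            sf.divider_voltage(0.0, divider)

    @given(st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=2,
                    max_size=20, unique=True))
    def test_output_monotone_decreasing_in_resistance(self, resistances):
        cfg = sf.DividerConfig(v_supply=5.0, r_load=1000.0)
        rs = sorted(resistances)
        vs = [sf.divider_voltage(r, cfg) for r in rs]
        assert all(a > b for a, b in zip(vs, vs[1:]))
        assert all(0.0 < v < 5.0 for v in vs)


class TestOptimalLoad:
    def test_standard_candidates_select_1k(self):
        assert sf.optimal_load([100, 220, 470, 1000, 2200, 4700, 10000],
                               (250.0, 4100.0), 5.0) == 1000.0

    def test_single_candidate(self):
        assert sf.optimal_load([500.0], (250.0, 4100.0)) == 500.0

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            sf.optimal_load([], (250.0, 4100.0))

    def test_fine_grid_peaks_at_geometric_mean(self):
        # independent continuum oracle: dense log grid vs sqrt(Rmin*Rmax)
        grid = np.logspace(1, 5, 40001)
        best = sf.optimal_load(grid, (250.0, 4100.0), 5.0)
        analytic = math.sqrt(250.0 * 4100.0)
        assert best == pytest.approx(analytic, rel=2e-4)


class TestDegreeOfHysteresis:
    def test_coincident_curves_give_zero(self):
        pts = [(0.0, 1.0), (0.04, 0.8), (0.08, 0.3)]
        assert sf.degree_of_hysteresis(pts, pts) == pytest.approx(0.0)

    def test_constructed_areas_match_printed_value(self):
        # loading area 1.0, unloading area 0.678 over [0, 1] -> DH 32.2%
        loading = [(0.0, 1.0), (1.0, 1.0)]
        unloading = [(0.0, 0.678), (1.0, 0.678)]
        assert sf.degree_of_hysteresis(loading, unloading) == pytest.approx(32.2)

    def test_half_area_gives_fifty_percent(self):
        loading = [(0.0, 1.0), (1.0, 1.0)]
        unloading = [(0.0, 0.5), (1.0, 0.5)]
        assert sf.degree_of_hysteresis(loading, unloading) == pytest.approx(50.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_invariant_to_uniform_value_rescaling(self, scale):
        loading = [(0.0, 2.0), (0.5, 1.5), (1.0, 1.0)]
        unloading = [(0.0, 1.4), (0.5, 1.0), (1.0, 0.9)]
        base = sf.degree_of_hysteresis(loading, unloading)
        scaled = sf.degree_of_hysteresis(
            [(p, v * scale) for p, v in loading],
            [(p, v * scale) for p, v in unloading])
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_mismatched_span_and_zero_area_rejected(self):
        with pytest.raises(ValueError):
            sf.degree_of_hysteresis([(0.0, 1.0), (1.0, 1.0)],
                                    [(0.0, 1.0), (0.5, 1.0)])
        with pytest.raises(ValueError):
            sf.degree_of_hysteresis([(0.0, 0.0), (1.0, 0.0)],
                                    [(0.0, 0.0), (1.0, 0.0)])

    def test_model_loop_has_positive_dh(self, curve):
        c = sf.calibrate_response(hysteresis_width=0.3)
        p = np.linspace(0.0, 0.12, 50)
        loading = list(zip(p, c.resistance(p, "loading")))
        unloading = list(zip(p, c.resistance(p, "unloading")))
        assert sf.degree_of_hysteresis(loading, unloading) > 0.0


class TestDrift:
    def test_fresh_sensor_unscaled(self):
        assert sf.drift_scale(DriftModel(), 0) == pytest.approx(1.0)

    def test_full_protocol_reaches_twenty_percent_decrease(self):
        assert sf.drift_scale(DriftModel(), 50_000) == pytest.approx(0.80, abs=0.01)

    def test_saturated_within_one_percent_by_8000_presses(self):
        m = DriftModel()
        assert sf.drift_scale(m, 8000) <= 0.80 * 1.01 + 1e-9
        assert drift_saturation_press(m) == pytest.approx(8000, rel=0.02)

    def test_scale_non_increasing_and_bounded(self):
        m = DriftModel()
        n = np.arange(0, 50_001, 100)
        s = sf.drift_scale(m, n)
        assert np.all(np.diff(s) <= 0)
        assert np.all(s >= m.asymptote_fraction)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sf.drift_scale(DriftModel(), -1)


class TestRepeatability:
    def test_identical_samples_fully_inside_band(self):
        assert sf.accuracy_statistic([5.0] * 10, 0.10) == 100.0

    def test_enumerated_example(self):
        # mean 107.5, band [96.75, 118.25]: only 100 and 110 inside
        assert sf.accuracy_statistic([90.0, 100.0, 110.0, 130.0], 0.10) == 50.0

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            sf.accuracy_statistic([], 0.10)

    @given(st.lists(st.floats(min_value=1.0, max_value=1e4), min_size=1,
                    max_size=40))
    def test_agrees_with_brute_force_count(self, samples):
        mean = sum(samples) / len(samples)
        brute = sum(1 for s in samples
                    if mean * 0.9 <= s <= mean * 1.1) / len(samples) * 100
        assert sf.accuracy_statistic(samples, 0.10) == pytest.approx(brute)

    def test_calibrated_noise_reproduces_92_percent(self, curve):
        model = calibrate_noise(band=0.10, coverage=0.92, seed=123)
        draws = model.draw(curve.resistance(0.05), 10_000)
        assert sf.accuracy_statistic(draws, 0.10) == pytest.approx(92.0, abs=2.0)

    def test_negative_spread_rejected(self):
        with pytest.raises(sf.CalibrationError):
            NoiseModel(relative_spread=-0.1)


class TestDigitize:
    def test_threshold_crossing(self):
        assert sf.digitize(4.0, 2.5) == (1, 4.0)
        assert sf.digitize(0.0, 2.5) == (0, 0.0)

    def test_unloaded_sensor_stays_below_threshold(self, curve, divider):
        v = sf.divider_voltage(curve.resistance(0.0), divider)
        assert v == pytest.approx(5.0 * 1000 / 5100, abs=1e-6)
        assert sf.digitize(v, 2.5)[0] == 0

    def test_default_threshold_separates_idle_from_step(self, curve, divider):
        thr = default_threshold(curve, divider)
        v_idle = sf.divider_voltage(curve.resistance(0.0), divider)
        v_step = sf.divider_voltage(curve.resistance(0.05), divider)
        assert v_idle < thr < v_step


class TestConfigAndExport:
    def test_curve_table_covers_both_branches(self, curve, divider):
        tbl = curve_table(curve, divider, n_points=11)
        assert list(tbl.columns) == ["pressure_kg_cm2", "r_loading_ohm",
                                     "r_unloading_ohm", "v_out_loading"]
        assert len(tbl) == 11

    def test_key_value_config_round_trip(self, tmp_path):
        cfg = tmp_path / "sensor.cfg"
        cfg.write_text("r_zero_ohm = 4100\nr_full_ohm = 250\n"
                       "p_full_kg_cm2 = 0.12  # full scale\n"
                       "v_supply = 5.0\nr_load_ohm = 1000\n")
        curve, divider, thr = sensor_from_config(read_sensor_config(cfg))
        assert curve.resistance(0.0) == pytest.approx(4100.0)
        assert divider.r_load == 1000.0
        assert 0.0 < thr < 5.0

    def test_unknown_config_key_rejected(self, tmp_path):
        cfg = tmp_path / "sensor.cfg"
        cfg.write_text("bogus = 1\n")
        with pytest.raises(ValueError):
            read_sensor_config(cfg)
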