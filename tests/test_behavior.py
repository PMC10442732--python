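"""Behavior metrics: episodes, sleep, wake-ups, toilet visits, accuracy."""

import pytest

import smartfloor as sf
from smartfloor.behavior import (AnalysisParams, BehaviorReport, analyze,
                                 comparison_table, count_toilet_visits,
                                 count_wakeups, detect_sleep_periods,
                                 episodes_from_trace, match_accuracy,
                                 zone_time_summary)
from smartfloor.tracking import ZoneSample


def stay(zone, mat, start, end, interval=0.5):
    """Stationary presence on one mat: samples every ``interval`` minutes."""
    out = []
    t = start
    while t <= end:
        out.append(ZoneSample(time=t, address=mat, quadrant=0, zone=zone))
        t += interval
    return out


def walk(zone, mats, start, interval=0.5):
    """Transit: one sample per mat, advancing every ``interval`` minutes."""
    return [ZoneSample(time=start + i * interval, address=m, quadrant=0,
                       zone=zone) for i, m in enumerate(mats)]


class TestEpisodes:
    def test_gap_beyond_debounce_splits_episodes(self):
        samples = stay("bedroom", 1, 0.0, 5.0) + stay("bedroom", 1, 20.0, 25.0)
        eps = episodes_from_trace(samples, debounce=2.0)
        assert len(eps) == 2

    def test_stationary_presence_accumulates_stay_minutes(self):
        eps = episodes_from_trace(stay("toilet", 5, 0.0, 6.0))
        assert len(eps) == 1
        assert eps[0].stay_minutes == pytest.approx(6.0)

    def test_walking_accumulates_no_stay(self):
        eps = episodes_from_trace(walk("activity", [1, 2, 3, 4, 5, 6], 0.0))
        assert len(eps) == 1
        assert eps[0].stay_minutes == pytest.approx(0.0)
        assert eps[0].dwell == pytest.approx(2.5)


class TestSleepAndWakeups:
    def test_never_in_bedroom_means_no_sleep(self):
        samples = stay("activity", 1, 200.0, 400.0)
        assert detect_sleep_periods(samples) == []
        assert count_wakeups(samples) == 0

    def test_single_night_is_one_period(self):
        samples = stay("bedroom", 1, 170.0, 650.0)
        periods = detect_sleep_periods(samples)
        assert len(periods) == 1
        start, end = periods[0]
        assert start == pytest.approx(180.0)  # clipped to the window
        assert end == pytest.approx(650.0)

    def test_one_nocturnal_exit_counts_one_wakeup(self):
        samples = (stay("bedroom", 1, 180.0, 300.0)
                   + stay("activity", 9, 310.0, 320.0)
                   + stay("bedroom", 1, 330.0, 650.0))
        assert count_wakeups(samples) == 1
        assert len(detect_sleep_periods(samples)) == 2

    def test_brief_movement_does_not_split_sleep(self):
        # 3-minute interruption < 5-minute movement tolerance
        samples = (stay("bedroom", 1, 180.0, 400.0)
                   + stay("bedroom", 1, 403.0, 650.0))
        assert len(detect_sleep_periods(samples)) == 1

    def test_daytime_exit_is_not_a_wakeup(self):
        samples = (stay("bedroom", 1, 180.0, 650.0)
                   + stay("activity", 9, 700.0, 720.0)
                   + stay("bedroom", 1, 1320.0, 1420.0))
        assert count_wakeups(samples) == 0

    def test_empty_trace_gives_empty_everything(self):
        assert detect_sleep_periods([]) == []
        assert count_wakeups([]) == 0
        assert count_toilet_visits([]) == (0, 0)


class TestToiletVisits:
    def test_one_daytime_visit(self):
        samples = stay("toilet", 3, 700.0, 706.0)
        assert count_toilet_visits(samples) == (1, 0)

    def test_nocturnal_onset_counts_during_sleep(self):
        samples = (stay("toilet", 3, 300.0, 306.0)
                   + stay("toilet", 3, 700.0, 706.0))
        assert count_toilet_visits(samples) == (2, 1)

    def test_walking_transit_is_not_a_visit(self):
        samples = walk("toilet", [3, 4, 5, 6, 7], 700.0)
        assert count_toilet_visits(samples) == (0, 0)


class TestDwellSummary:
    def test_empty_trace_all_zeros(self):
        assert zone_time_summary([]) == {z: 0.0 for z in
                                         ("bedroom", "toilet", "entrance",
                                          "activity")}

    def test_constant_bedroom_presence(self):
        summary = zone_time_summary(stay("bedroom", 1, 100.0, 110.0))
        assert summary["bedroom"] == pytest.approx(10.0)
        assert summary["toilet"] == 0.0

    def test_pipeline_dwell_matches_generator_bookkeeping(self, fixture_room):
        run = sf.run_scenario("normal", seed=2, room=fixture_room)
        measured = zone_time_summary(run.zone_samples)
        booked = run.trajectory.meta["stay_minutes"]
        entries = run.truth["zone_entries"]
        transit_budget = 1440.0 - sum(booked.values())
        for zone, minutes in measured.items():
            assert minutes >= booked[zone] - 2.0 * entries[zone]
            assert minutes <= booked[zone] + 2.0 * entries[zone] + transit_budget


class TestMatchAccuracy:
    def _report(self, entries):
        return BehaviorReport(sleep_periods=[], wakeup_count=0,
                              toilet_visits_total=0,
                              toilet_visits_during_sleep=0, dwell_minutes={},
                              zone_entries=entries)

    def test_perfect_match_is_100(self):
        truth = {"bedroom": 2, "toilet": 4, "entrance": 2, "activity": 6}
        assert match_accuracy(self._report(dict(truth)), truth) == 100.0

    def test_three_of_four_is_75(self):
        truth = {"bedroom": 2, "toilet": 4, "entrance": 2, "activity": 6}
        got = dict(truth, toilet=5)
        assert match_accuracy(self._report(got), truth) == 75.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            match_accuracy(self._report({}), {"zone_entries": {}})

    def test_comparison_table_mirrors_per_zone_counts(self):
        truth = {"bedroom": 2, "toilet": 4, "entrance": 2, "activity": 6}
        df = comparison_table(self._report(dict(truth, toilet=5)), truth)
        assert len(df) == 4
        assert df.loc[df.zone == "toilet", "match"].item() is False
        assert df.loc[df.zone == "bedroom", "match"].item() is True


class TestInvariances:
    def test_metrics_invariant_to_time_translation(self):
        samples = (stay("bedroom", 1, 180.0, 650.0)
                   + stay("toilet", 3, 700.0, 706.0)
                   + stay("bedroom", 1, 1320.0, 1420.0))
        base = analyze(samples)
        delta = 37.25
        shifted = [ZoneSample(s.time + delta, s.address, s.quadrant, s.zone)
                   for s in samples]
        lo, hi = AnalysisParams().sleep_window
        params = AnalysisParams(sleep_window=(lo + delta, hi + delta))
        moved = analyze(shifted, params)
        assert moved.wakeup_count == base.wakeup_count
        assert moved.toilet_visits_total == base.toilet_visits_total
        assert moved.zone_entries == base.zone_entries
        assert len(moved.sleep_periods) == len(base.sleep_periods)

    def test_during_sleep_never_exceeds_total(self):
        with pytest.raises(ValueError):
            BehaviorReport(sleep_periods=[], wakeup_count=0,
                           toilet_visits_total=1, toilet_visits_during_sleep=2,
                           dwell_minutes={}, zone_entries={})
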