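"""Episode model: effective escalations, chaining, tiling, classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wardalert.cohort import ClinicalEvent
from wardalert.episodes import (
    ContingencyTable,
    CoverageError,
    EffectiveEoc,
    OrderingError,
    WarningPeriod,
    build_warning_periods,
    censor_time,
    classify,
    clip_periods,
    derive_effective_eocs,
    evaluate_admission,
    segment_negative_time,
)
from wardalert.scoring import ScoreSeries

from conftest import make_admission
from oracles import effective_eocs_sweep, episodes_sweep


def ev(*pairs):
    return [ClinicalEvent(t, k) for t, k in pairs]


class TestEffectiveEocs:
    @pytest.mark.parametrize("events,expected_times", [
        ([(1000, "rrt"), (1600, "rrt")], [1000]),            # < 24 h apart: one escalation
        ([(1000, "rrt"), (3000, "rrt")], [1000, 3000]),      # >= 24 h apart: two
        ([(500, "death")], [500]),
        ([(500, "death"), (2500, "rrt")], [500]),            # non-RRT closes follow-up
        ([(500, "icu_unplanned"), (3000, "rrt")], [500]),
        ([(100, "monitoring_stop"), (500, "rrt")], []),      # censored before escalation
        ([(500, "rrt"), (600, "icu_unplanned")], [500]),     # non-RRT too soon: not counted
        ([(500, "rrt"), (2000, "rrt"), (3500, "rrt")], [500, 2000, 3500]),
        ([(500, "rrt"), (2000, "discharge"), (3000, "rrt")], [500]),
    ])
    def test_repeat_escalation_rule(self, events, expected_times):
        eocs = derive_effective_eocs(ev(*events))
        assert [e.t_min for e in eocs] == expected_times
        assert [e.sequence_index for e in eocs] == list(range(1, len(eocs) + 1))

    def test_unordered_events_rejected(self):
        with pytest.raises(OrderingError):
            derive_effective_eocs(ev((1000, "rrt"), (500, "rrt")))

    def test_matches_rule_engine_over_random_sequences(self):
        rng = np.random.default_rng(100)
        kinds = ["rrt", "rrt", "icu_unplanned", "emergency_surgery", "death",
                 "monitoring_stop", "discharge"]
        for _ in range(400):
            n = rng.integers(1, 6)
            times = np.sort(rng.integers(0, 6000, size=n))
            events = [(int(t), kinds[rng.integers(len(kinds))]) for t in times]
            got = [e.t_min for e in derive_effective_eocs(ev(*events))]
            assert got == effective_eocs_sweep(events)


class TestWarningPeriods:
    def test_chaining_extends_four_hours_from_latest_alert(self):
        (p,) = build_warning_periods([0, 180], [])
        assert (p.start, p.end, p.alert_times) == (0, 420, [0, 180])

    def test_alert_at_boundary_opens_new_period(self):
        p1, p2 = build_warning_periods([0, 240], [])
        assert (p1.start, p1.end) == (0, 240)
        assert (p2.start, p2.end) == (240, 480)

    def test_truncation_at_escalation(self):
        eocs = [EffectiveEoc(100, "death", 1)]
        (p,) = build_warning_periods([0], eocs)
        assert (p.start, p.end, p.truncated_by_eoc) == (0, 100, True)
        assert p.contains_eoc_time(100)
        # alerts after the final non-RRT escalation are discarded
        assert build_warning_periods([0, 150], eocs) == build_warning_periods([0], eocs)

    def test_chaining_resumes_after_rrt_escalation(self):
        eocs = [EffectiveEoc(100, "rrt", 1)]
        p1, p2 = build_warning_periods([0, 150], eocs)
        assert (p1.start, p1.end, p1.truncated_by_eoc) == (0, 100, True)
        assert (p2.start, p2.end, p2.truncated_by_eoc) == (150, 390, False)

    def test_rejects_unsorted_alerts(self):
        with pytest.raises(OrderingError):
            build_warning_periods([100, 50], [])

    @given(st.lists(st.integers(0, 4000), min_size=1, max_size=25, unique=True))
    def test_chaining_is_idempotent_on_its_own_output(self, alerts):
        periods = build_warning_periods(sorted(alerts), [])
        again = build_warning_periods(
            sorted(t for p in periods for t in p.alert_times), [])
        assert [(p.start, p.end) for p in again] == [(p.start, p.end) for p in periods]


class TestNegativeSegments:
    def test_full_day_without_alerts_gives_three_blocks(self):
        a = make_admission(los_min=1440)
        segs = segment_negative_time(a, [])
        assert [(s.start, s.end) for s in segs] == [(0, 480), (480, 960), (960, 1440)]

    def test_remainder_segment_after_warning_period(self):
        a = make_admission(los_min=720)
        segs = segment_negative_time(a, [WarningPeriod(0, 240, [0])])
        assert [(s.start, s.end) for s in segs] == [(240, 720)]

    def test_overlapping_periods_rejected(self):
        a = make_admission(los_min=1440)
        with pytest.raises(Exception, match="overlap"):
            segment_negative_time(a, [WarningPeriod(0, 300, [0]),
                                      WarningPeriod(200, 500, [200])])

    def test_censoring_at_monitoring_stop(self):
        a = make_admission(los_min=2880,
                           events=ev((1000, "monitoring_stop"), (2880, "discharge")))
        segs = segment_negative_time(a, [])
        assert segs[-1].end == 1000


class TestClassification:
    def test_escalation_inside_period_is_true_positive(self):
        eocs = [EffectiveEoc(400, "rrt", 1)]
        periods = [WarningPeriod(0, 420, [0, 180])]
        table, ann_p, _ = classify(periods, [NegativeSegmentAt(420, 900)], eocs)
        assert (table.tp, table.fp, table.fn) == (1, 0, 0)
        assert ann_p[0].classification == "TP" and ann_p[0].eoc_t == 400

    def test_escalation_in_following_segment_counts_fp_and_fn(self):
        eocs = [EffectiveEoc(500, "rrt", 1)]
        table, ann_p, ann_s = classify([WarningPeriod(0, 420, [0])],
                                       [NegativeSegmentAt(420, 900)], eocs)
        assert (table.tp, table.fp, table.tn, table.fn) == (0, 1, 0, 1)
        assert ann_p[0].classification == "FP" and ann_s[0].classification == "FN"

    def test_uncovered_escalation_raises(self):
        with pytest.raises(CoverageError):
            classify([], [NegativeSegmentAt(0, 100)], [EffectiveEoc(500, "rrt", 1)])

    def test_contingency_counts_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            ContingencyTable(tp=-1, fp=0, tn=0, fn=0)


def NegativeSegmentAt(start, end):
    from wardalert.episodes import NegativeSegment
    return NegativeSegment(start, end)


def _random_scenario(rng):
    censor_los = int(rng.integers(1000, 8000))
    events = []
    if rng.random() < 0.6:
        n_eoc = int(rng.integers(1, 3))
        t = int(rng.integers(200, censor_los))
        kind = str(rng.choice(["rrt", "icu_unplanned", "death", "emergency_surgery"]))
        events.append((t, kind))
        if n_eoc == 2 and kind == "rrt":
            t2 = int(rng.integers(t + 1, censor_los + 1))
            events.append((t2, str(rng.choice(["rrt", "death"]))))
    terminal_kinds = [k for _, k in events if k in ("death",)]
    los = censor_los
    event_objs = ev(*events) + ([] if terminal_kinds else [ClinicalEvent(los, "discharge")])
    n_alerts = int(rng.integers(0, 25))
    alerts = sorted(set(int(x) for x in rng.integers(0, los, size=n_alerts)))
    a = make_admission(los_min=los, sample_times=np.arange(0, 10), events=event_objs)
    return a, alerts


def _run_library(a, alerts):
    eocs = derive_effective_eocs(a.events)
    series_alerts = alerts
    return evaluate_admission(a, [t for t in series_alerts], "continuous")


def test_episode_model_matches_minute_sweep_on_random_inputs():
    """Interval-arithmetic construction equals the brute-force minute sweep."""
    rng = np.random.default_rng(2024)
    for _ in range(250):
        a, alerts = _random_scenario(rng)
        eocs = derive_effective_eocs(a.events)
        result = evaluate_admission(a, alerts, "continuous")
        oracle_p, oracle_s, oracle_c = episodes_sweep(
            alerts, [(e.t_min, e.kind) for e in eocs], censor_time(a, eocs))
        assert [(p.start, p.end, p.truncated_by_eoc) for p in result.periods] == oracle_p
        assert [(s.start, s.end) for s in result.segments] == oracle_s
        t = result.table
        assert {"tp": t.tp, "fp": t.fp, "tn": t.tn, "fn": t.fn} == oracle_c
        assert t.tp + t.fn == len(eocs)  # conservation on every input


def test_periods_and_segments_tile_the_evaluable_timeline():
    rng = np.random.default_rng(55)
    for _ in range(100):
        a, alerts = _random_scenario(rng)
        result = evaluate_admission(a, alerts, "continuous")
        intervals = sorted([(p.start, min(p.end, result.censor)) for p in result.periods]
                           + [(s.start, s.end) for s in result.segments])
        intervals = [iv for iv in intervals if iv[1] > iv[0]]
        cursor = 0
        for s, e in intervals:
            assert s == cursor, "gap or overlap in tiling"
            cursor = e
        assert cursor == result.censor
        for s in result.segments:
            assert s.end - s.start <= 480


def test_lower_threshold_never_shrinks_warning_time_or_tp(small_cohort):
    """Alert-threshold monotonicity for the continuous scenario."""
    from wardalert.scoring import score_continuous
    checked = 0
    for a in small_cohort[:25]:
        series = score_continuous(a)
        e = series.entries
        for hi, lo in [(3.0, 2.0), (2.5, 1.5)]:
            alerts_hi = e.loc[e["valid"] & (e["score"] >= hi), "t_min"].astype(int).tolist()
            alerts_lo = e.loc[e["valid"] & (e["score"] >= lo), "t_min"].astype(int).tolist()
            r_hi = evaluate_admission(a, alerts_hi, "continuous")
            r_lo = evaluate_admission(a, alerts_lo, "continuous")
            covered_hi = set()
            for p in r_hi.periods:
                covered_hi.update(range(p.start, p.end))
            covered_lo = set()
            for p in r_lo.periods:
                covered_lo.update(range(p.start, p.end))
            assert covered_hi <= covered_lo
            assert r_lo.table.tp >= r_hi.table.tp
            checked += 1
    assert checked > 0
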