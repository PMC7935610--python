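"""Cascade interval construction, labeling, triggers, and per-case counts."""

import numpy as np
import pandas as pd
import pytest

from cascadeflow import (
    CascadeConfig,
    CascadeInterval,
    CascadeSet,
    bin_counts,
    cascade_triggers,
    cascades_per_case,
    exact_segmentation,
    find_cascades,
    from_frame,
    interval_jaccard,
    label_events,
    segment_rates,
)
from cascadeflow.cascade import RateSegment
from cascadeflow.errors import ConsistencyError, ParameterError


def make_segments(spec):
    """Build contiguous RateSegments from (duration, rate) pairs."""
    out, t = [], 0.0
    for duration, rate in spec:
        out.append(RateSegment(t, t + duration, rate, int(round(rate * duration))))
        t += duration
    return out


class TestSegmentRates:
    def test_counts_to_rates(self):
        series = bin_counts([3.1, 3.2, 3.3, 4.5, 4.6, 4.7, 5.5, 5.6, 5.7], 1.0, 0.0, 6.0)
        assert series.counts.tolist() == [0, 0, 0, 3, 3, 3]
        result = exact_segmentation(series.rates, beta=1.0)
        segments = segment_rates(series, result)
        assert result.changepoints == [3]
        assert segments[0].start_time == 0.0 and segments[0].end_time == 3.0
        assert segments[0].mean_rate == pytest.approx(0.0)
        assert segments[1].start_time == 3.0 and segments[1].end_time == 6.0
        assert segments[1].mean_rate == pytest.approx(3.0)

    def test_no_changepoints_single_segment(self):
        series = bin_counts([0.5, 1.5], 1.0, 0.0, 4.0)
        result = exact_segmentation(series.rates, beta=100.0)
        segments = segment_rates(series, result)
        assert len(segments) == 1
        assert (segments[0].start_time, segments[0].end_time) == (0.0, 4.0)

    def test_rates_match_brute_force_recount(self, rng):
        times = rng.uniform(0, 20, size=150)
        series = bin_counts(times, 1.0, 0.0, 20.0)
        result = exact_segmentation(series.rates, beta=3.0)
        for seg in segment_rates(series, result):
            count = np.sum((times >= seg.start_time) & (times < seg.end_time))
            assert seg.mean_rate == pytest.approx(count / seg.duration)

    def test_length_mismatch_rejected(self):
        series = bin_counts([0.5], 1.0, 0.0, 3.0)
        result = exact_segmentation([1.0, 2.0], beta=1.0)
        with pytest.raises(ParameterError):
            segment_rates(series, result)


class TestFindCascades:
    def test_long_high_rate_segment_qualifies(self):
        segs = make_segments([(10, 0.2), (4, 1.2), (10, 0.1)])
        cascades = find_cascades(segs, CascadeConfig())
        assert len(cascades) == 1
        assert (cascades[0].start, cascades[0].end) == (10.0, 14.0)

    def test_short_high_rate_segment_rejected(self):
        segs = make_segments([(10, 0.2), (2, 1.2), (10, 0.1)])
        assert find_cascades(segs, CascadeConfig()) == []

    def test_adjacent_high_segments_merge(self):
        segs = make_segments([(5, 0.2), (2, 1.5), (2, 1.1), (5, 0.2)])
        cascades = find_cascades(segs, CascadeConfig())
        assert len(cascades) == 1
        assert (cascades[0].start, cascades[0].end) == (5.0, 9.0)
        assert cascades[0].duration == pytest.approx(4.0)

    def test_no_merge_flag_scores_segments_individually(self):
        segs = make_segments([(5, 0.2), (2, 1.5), (2, 1.1), (5, 0.2)])
        assert find_cascades(segs, CascadeConfig(), merge_adjacent=False) == []
        segs = make_segments([(5, 0.2), (3, 1.5), (3, 1.1), (5, 0.2)])
        assert len(find_cascades(segs, CascadeConfig(), merge_adjacent=False)) == 2

    def test_rule_thresholds_by_construction(self):
        segs = make_segments([(3, 0.2), (4, 2.0), (2, 0.1), (5, 1.0), (3, 0.4)])
        for cascade in find_cascades(segs, CascadeConfig()):
            assert cascade.duration >= 3.0
            assert cascade.mean_rate >= 1.0

    def test_monotone_in_threshold_and_duration(self):
        segs = make_segments(
            [(4, 0.2), (3, 1.1), (2, 0.3), (5, 1.6), (4, 0.2), (3, 2.5)]
        )
        counts_r = [
            len(find_cascades(segs, CascadeConfig(rate_threshold=r)))
            for r in [0.5, 1.0, 1.5, 2.0, 3.0]
        ]
        counts_w = [
            len(find_cascades(segs, CascadeConfig(min_duration=w)))
            for w in [1.0, 3.0, 4.0, 6.0]
        ]
        assert counts_r == sorted(counts_r, reverse=True)
        assert counts_w == sorted(counts_w, reverse=True)


class TestLabelAndTriggers:
    @pytest.fixture
    def labeled_setup(self):
        events = from_frame(
            pd.DataFrame(
                {
                    "Time": [0.0, 10.0, 10.2, 10.9, 14.0, 20.0],
                    "Case": ["A"] * 6,
                    "EventType": ["EQ", "TRN", "EQ", "COM", "EQ", "COO"],
                }
            )
        )
        cascades = CascadeSet(
            intervals={"A": [CascadeInterval(10.0, 14.0, 1.2, 5)]}, cases=["A"]
        )
        return events, cascades

    def test_half_open_membership(self, labeled_setup):
        events, cascades = labeled_setup
        labeled = label_events(events, cascades)
        flags = labeled.df["InCascade"].tolist()
        # event at 10.0 inside, event at 14.0 outside
        assert flags == [False, True, True, True, False, False]

    def test_case_without_cascades_all_false(self, labeled_setup):
        events, _ = labeled_setup
        empty = CascadeSet(intervals={}, cases=["A"])
        assert not label_events(events, empty).df["InCascade"].any()

    def test_trigger_is_earliest_in_interval_event(self, labeled_setup):
        events, cascades = labeled_setup
        cascades, tally = cascade_triggers(events, cascades)
        assert cascades.for_case("A")[0].trigger == "TRN"
        assert cascades.for_case("A")[0].n_events == 3
        assert tally == {"TRN": 1}

    def test_trigger_tally_counts_types(self):
        events = from_frame(
            pd.DataFrame(
                {
                    "Time": [1.0, 30.0, 1.0, 1.0],
                    "Case": ["A", "A", "B", "C"],
                    "EventType": ["TRN", "TRN", "TRN", "COM"],
                }
            )
        )
        cascades = CascadeSet(
            intervals={
                "A": [CascadeInterval(0, 4, 1.2, 5), CascadeInterval(28, 33, 1.5, 6)],
                "B": [CascadeInterval(0, 4, 1.1, 4)],
                "C": [CascadeInterval(0, 4, 1.1, 4)],
            },
            cases=["A", "B", "C"],
        )
        _, tally = cascade_triggers(events, cascades)
        assert tally == {"TRN": 3, "COM": 1}

    def test_eventless_cascade_is_inconsistent(self):
        events = from_frame(
            pd.DataFrame({"Time": [0.0, 50.0], "Case": ["A", "A"],
                          "EventType": ["EQ", "EQ"]})
        )
        cascades = CascadeSet(
            intervals={"A": [CascadeInterval(10.0, 14.0, 1.2, 5)]}, cases=["A"]
        )
        with pytest.raises(ConsistencyError):
            cascade_triggers(events, cascades)

    def test_label_agrees_with_brute_force_membership(self, rng):
        times = np.sort(rng.uniform(0, 60, size=300))
        events = from_frame(pd.DataFrame({"Time": times, "Case": "X"}))
        ivs = [CascadeInterval(10.0, 14.0, 2.0, 8), CascadeInterval(40.0, 47.0, 1.5, 10)]
        cascades = CascadeSet(intervals={"X": ivs}, cases=["X"])
        labeled = label_events(events, cascades)
        rel = labeled.relative_time
        expected = [any(iv.contains(t) for iv in ivs) for t in rel]
        assert labeled.df["InCascade"].tolist() == expected


class TestPerCaseCounts:
    def test_histogram_includes_zero_cascade_cases(self):
        cascades = CascadeSet(
            intervals={
                "A": [CascadeInterval(0, 4, 1.2, 5)],
                "C": [CascadeInterval(0, 4, 1.2, 5), CascadeInterval(10, 14, 1.2, 5)],
            },
            cases=["A", "B", "C"],
        )
        dist = cascades_per_case(cascades)
        assert dist["per_case"] == {"A": 1, "B": 0, "C": 2}
        assert dist["histogram"] == {0: 1, 1: 1, 2: 1}
        assert dist["percentages"][1] == pytest.approx(100 / 3)

    def test_no_cascades_anywhere(self):
        dist = cascades_per_case(CascadeSet(intervals={}, cases=list("abcd")))
        assert dist["histogram"] == {0: 4}
        assert dist["percentages"] == {0: 100.0}


def test_interval_jaccard_basics():
    assert interval_jaccard((0, 4), (2, 6)) == pytest.approx(2 / 6)
    assert interval_jaccard((0, 4), (0, 4)) == 1.0
    assert interval_jaccard((0, 1), (5, 6)) == 0.0
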