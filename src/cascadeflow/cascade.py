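"""Cascade identification from segmented rate series.

A *cascade* is a sustained burst of events: a period whose mean event
rate stays at or above a threshold r* (default 1 event/min) for at least
a minimum duration w (default 3 min).  Construction is segment-based:
the changepoint segmentation of the binned rate series is filtered by
the rate rule, adjacent high-rate segments are merged into maximal runs,
and runs long enough to satisfy the duration rule become cascade
intervals.  Interval membership is half-open ``[t_start, t_end)``.

The *trigger* of a cascade is the event type of the earliest event
inside the interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConsistencyError, ParameterError
from .io import CASE, EVENT_TYPE, IN_CASCADE, RELATIVE_TIME, EventTable
from .regularize import RegularizedSeries
from .changepoint import ChangepointResult


@dataclass(frozen=True)
class CascadeConfig:
    """Rate/duration rule: mean rate ≥ ``rate_threshold`` events/min
    sustained for ≥ ``min_duration`` minutes."""

    rate_threshold: float = 1.0
    min_duration: float = 3.0

    def __post_init__(self):
        if self.rate_threshold <= 0:
            raise ParameterError("rate_threshold must be > 0")
        if self.min_duration <= 0:
            raise ParameterError("min_duration must be > 0")


@dataclass
class RateSegment:
    """One inter-changepoint run of the regularized series."""

    start_time: float
    end_time: float
    mean_rate: float
    count: int

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class CascadeInterval:
    """A detected cascade: ``[start, end)`` in relative minutes."""

    start: float
    end: float
    mean_rate: float
    count: int
    trigger: Optional[str] = None
    n_events: Optional[int] = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class CascadeSet:
    """Cascade intervals per case, over an explicit case universe.

    ``cases`` lists every case in the study, including those without
    cascades, so per-case histograms use the right denominator.
    """

    intervals: dict = field(default_factory=dict)  # case -> list[CascadeInterval]
    cases: list = field(default_factory=list)

    def __post_init__(self):
        for case, ivs in self.intervals.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ConsistencyError(
                        f"overlapping cascade intervals in case {case!r}"
                    )
        for case in self.intervals:
            if case not in self.cases:
                self.cases.append(case)

    @property
    def n_cascades(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def for_case(self, case) -> list[CascadeInterval]:
        return self.intervals.get(case, [])

    def all_intervals(self):
        for case in self.cases:
            for iv in self.intervals.get(case, []):
                yield case, iv


def segment_rates(
    series: RegularizedSeries, result: ChangepointResult
) -> list[RateSegment]:
    """Convert a changepoint result on a binned series into timed segments.

    Each segment's mean rate is its total event count divided by its
    duration in minutes (bin-boundary times, truncated final bin
    respected).
    """
    if result.n != series.n_bins:
        raise ParameterError(
            f"changepoint result is for n={result.n} but series has {series.n_bins} bins"
        )
    segments = []
    for a, b in result.segments():  # 1-based inclusive bin indices
        start = float(series.bin_starts[a - 1])
        end = float(series.bin_end(b - 1))
        count = int(series.counts[a - 1 : b].sum())
        segments.append(RateSegment(start, end, count / (end - start), count))
    return segments


def find_cascades(
    segments: list[RateSegment],
    config: CascadeConfig = CascadeConfig(),
    merge_adjacent: bool = True,
) -> list[CascadeInterval]:
    """Apply the rate/duration rule to contiguous rate segments.

    Adjacent segments whose mean rate meets the threshold are merged
    into maximal runs (unless ``merge_adjacent`` is False, in which case
    each high-rate segment is judged on its own); a run qualifies as a
    cascade iff its total duration meets ``min_duration``.
    """
    r_star, w = config.rate_threshold, config.min_duration
    high = [s for s in segments if s.mean_rate >= r_star]
    if not merge_adjacent:
        return [
            CascadeInterval(s.start_time, s.end_time, s.mean_rate, s.count)
            for s in high
            if s.duration >= w
        ]

    runs: list[list[RateSegment]] = []
    current: list[RateSegment] = []
    for seg in segments:
        if seg.mean_rate >= r_star and (
            not current or current[-1].end_time == seg.start_time
        ):
            current.append(seg)
        else:
            if current:
                runs.append(current)
            current = [seg] if seg.mean_rate >= r_star else []
    if current:
        runs.append(current)
    cascades = []
    for run in runs:
        start, end = run[0].start_time, run[-1].end_time
        count = sum(s.count for s in run)
        if end - start >= w:
            cascades.append(CascadeInterval(start, end, count / (end - start), count))
    return cascades


def label_events(events: EventTable, cascades: CascadeSet) -> EventTable:
    """Flag each event as in-cascade via half-open interval membership.

    Returns a new table with a boolean ``InCascade`` column; the clock is
    ``RelativeTime``, matching the cascade intervals.
    """
    df = events.df.copy()
    flags = np.zeros(len(df), dtype=bool)
    rel = df[RELATIVE_TIME].to_numpy(dtype=float)
    if CASE in df.columns:
        case_vals = df[CASE].to_numpy()
        for case in cascades.cases:
            ivs = cascades.for_case(case)
            if not ivs:
                continue
            sel = case_vals == case
            for iv in ivs:
                flags |= sel & (rel >= iv.start) & (rel < iv.end)
    else:
        for iv in cascades.for_case(None):
            flags |= (rel >= iv.start) & (rel < iv.end)
    df[IN_CASCADE] = flags
    return EventTable(df)


def cascade_triggers(
    events: EventTable, cascades: CascadeSet
) -> tuple[CascadeSet, Counter]:
    """Attribute each cascade to its first in-interval event's type.

    Fills ``trigger`` and ``n_events`` on every interval and returns the
    tally of triggers by type.  A cascade containing zero events violates
    the rate rule and raises :class:`ConsistencyError`.
    """
    if not events.has_event_type:
        raise ParameterError("events carry no EventType column to attribute triggers")
    tally: Counter = Counter()
    for case, iv in cascades.all_intervals():
        rel = events.case_relative_times(case)
        if events.has_case:
            sub = events.df.loc[events.df[CASE] == case]
        else:
            sub = events.df
        inside = (rel >= iv.start) & (rel < iv.end)
        if not inside.any():
            raise ConsistencyError(
                f"cascade [{iv.start}, {iv.end}) in case {case!r} contains no events"
            )
        # earliest event; ties resolved by table order (stable argmin)
        pos = np.flatnonzero(inside)
        first = pos[np.argmin(rel[inside])]
        iv.trigger = sub.iloc[first][EVENT_TYPE]
        iv.n_events = int(inside.sum())
        tally[iv.trigger] += 1
    return cascades, tally


def cascades_per_case(cascades: CascadeSet) -> dict:
    """Distribution of cascade counts over the full case universe.

    Returns ``{"per_case": {case: k}, "histogram": {k: n_cases},
    "percentages": {k: 100·n_cases/total}}``; zero-cascade cases count.
    """
    per_case = {case: len(cascades.for_case(case)) for case in cascades.cases}
    histogram = dict(sorted(Counter(per_case.values()).items()))
    total = len(per_case)
    percentages = {
        k: (100.0 * v / total if total else 0.0) for k, v in histogram.items()
    }
    return {"per_case": per_case, "histogram": histogram, "percentages": percentages}


def interval_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Jaccard overlap of two half-open intervals (0 when disjoint)."""
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union > 0 else 0.0


def write_cascades_bed(cascades: CascadeSet, path) -> None:
    """Export intervals as a BED-like TSV: case, start, end, trigger, n_events, mean_rate."""
    with open(path, "w") as fh:
        fh.write("case\tstart_min\tend_min\ttrigger\tn_events\tmean_rate\n")
        for case, iv in cascades.all_intervals():
            fh.write(
                f"{case}\t{iv.start:g}\t{iv.end:g}\t{iv.trigger or '.'}"
                f"\t{iv.n_events if iv.n_events is not None else '.'}\t{iv.mean_rate:.4f}\n"
            )
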