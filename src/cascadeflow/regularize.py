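"""Regularization of irregular event times into fixed-interval count series.

Changepoint algorithms assume regularly spaced observations; event data
are not.  The bridge is counting events in fixed-width bins over a
user-specified range, which yields a count (and rate) series indexed by
bin start time.  Bins are half-open ``[a, b)``: an event exactly on a
boundary belongs to the later bin, and an event at exactly the range end
is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass
class RegularizedSeries:
    """Fixed-width bin counts and rates over ``[range_start, range_end)``.

    The final bin is truncated at ``range_end`` when the range is not a
    whole number of bins; its rate uses the truncated width.
    """

    range_start: float
    range_end: float
    bin_width: float
    bin_starts: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_widths(self) -> np.ndarray:
        """Effective width per bin (last may be truncated)."""
        ends = np.minimum(self.bin_starts + self.bin_width, self.range_end)
        return ends - self.bin_starts

    @property
    def rates(self) -> np.ndarray:
        """Events per minute per bin."""
        return self.counts / self.bin_widths

    def bin_end(self, i: int) -> float:
        return min(self.bin_starts[i] + self.bin_width, self.range_end)


def bin_counts(
    times,
    bin_width: float,
    range_start: float,
    range_end: float,
) -> RegularizedSeries:
    """Count events in fixed-width half-open bins.

    Parameters
    ----------
    times
        Event times in minutes (any order; need not be sorted).
    bin_width
        Bin width in minutes, > 0.
    range_start, range_end
        Half-open counting range ``[range_start, range_end)``; events
        outside are excluded.

    An empty ``times`` yields an all-zero series, not an error.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    if range_end <= range_start:
        raise ParameterError(
            f"range_end ({range_end}) must exceed range_start ({range_start})"
        )
    t = np.asarray(times, dtype=float)
    n_bins = int(np.ceil((range_end - range_start) / bin_width))
    bin_starts = range_start + bin_width * np.arange(n_bins)

    t = t[(t >= range_start) & (t < range_end)]
    idx = np.floor((t - range_start) / bin_width).astype(int)
    # guard: times infinitesimally below range_end can round up to n_bins
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(int)
    return RegularizedSeries(range_start, range_end, bin_width, bin_starts, counts)


def default_range(times, bin_width: float = 1.0) -> tuple[float, float]:
    """Default counting range ``[0, end)`` for relative event times.

    ``end`` is the maximum time rounded up to a whole bin; when the
    maximum falls exactly on a bin boundary one extra bin is added so the
    half-open range still contains the last event.
    """
    t = np.asarray(times, dtype=float)
    if len(t) == 0:
        return 0.0, bin_width
    t_max = float(t.max())
    n = int(np.floor(t_max / bin_width)) + 1
    return 0.0, n * bin_width


def sliding_rate(times, window: float, step: float):
    """Sliding-window event rates, for sensitivity checks.

    Windows ``[s, s + window)`` advance by ``step`` starting from the
    floor of the first event time, as long as ``s`` does not exceed the
    last event.  Returns a list of ``(window_start, rate)`` pairs with
    rate in events per minute.  Empty input yields an empty list.
    """
    if window <= 0:
        raise ParameterError(f"window must be > 0, got {window}")
    if step <= 0:
        raise ParameterError(f"step must be > 0, got {step}")
    t = np.sort(np.asarray(times, dtype=float))
    if len(t) == 0:
        return []
    out = []
    s = float(np.floor(t[0]))
    t_last = t[-1]
    while s <= t_last:
        count = int(np.count_nonzero((t >= s) & (t < s + window)))
        out.append((s, count / window))
        s += step
    return out
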