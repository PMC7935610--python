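"""Penalized change-in-mean segmentation, implemented from first principles.

Four detectors over a numeric series y_1..y_n:

``amoc``
    at-most-one-change: a single-split scan of the cost reduction
    Δ(τ) = C(1, n) − C(1, τ) − C(τ+1, n), accepted when max Δ > β;
``binseg``
    greedy binary segmentation — repeatedly apply the best single split
    to whichever current segment offers the largest Δ (approximate);
``exact_segmentation``
    optimal partitioning by dynamic programming:
    F(0) = −β,  F(t) = min_{0 ≤ s < t} [F(s) + C(y_{s+1..t}) + β],
    globally optimal over all 2^(n−1) segmentations;
``pelt``
    the same recursion restricted to a pruned candidate set — after
    computing F(t), every s with F(s) + C(s+1, t) > F(t) is discarded,
    which is safe for the SSE cost (pruning constant K = 0) and leaves
    the result identical to ``exact_segmentation``.

The segment cost C is the within-segment sum of squared deviations from
the segment mean (Normal likelihood, change in mean), evaluated in O(1)
from prefix sums.  Changepoint indices are 1-based and mark the *last*
element of their segment, matching the convention of the classical R
implementations so results can be cross-checked.

Ties: when two segmentations reach the same objective, the one with
fewer changepoints wins; among equals, the lexicographically smallest
changepoint vector.  This makes PELT ≡ EXACT a testable identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ParameterError

_METHODS = ("AMOC", "BINSEG", "EXACT", "PELT")

#: relative tolerance for objective ties
_EPS = 1e-9


class SegmentCost:
    """O(1) sum-of-squared-error segment costs from prefix sums."""

    def __init__(self, series: Sequence[float]):
        y = np.asarray(series, dtype=float)
        if y.ndim != 1:
            raise ParameterError("series must be one-dimensional")
        self.n = len(y)
        self._s1 = np.concatenate([[0.0], np.cumsum(y)])
        self._s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def cost(self, a: int, b: int) -> float:
        """SSE of y_a..y_b (1-based, inclusive)."""
        if not (1 <= a <= b <= self.n):
            raise ParameterError(f"invalid segment [{a}, {b}] for n={self.n}")
        m = b - a + 1
        s = self._s1[b] - self._s1[a - 1]
        q = self._s2[b] - self._s2[a - 1]
        # rounding can push the difference a hair below zero
        return max(q - s * s / m, 0.0)

    def mean(self, a: int, b: int) -> float:
        if not (1 <= a <= b <= self.n):
            raise ParameterError(f"invalid segment [{a}, {b}] for n={self.n}")
        return (self._s1[b] - self._s1[a - 1]) / (b - a + 1)


def cost_sse(series: Sequence[float], a: int, b: int) -> float:
    """Sum of squared deviations from the mean over ``series[a..b]`` (1-based)."""
    return SegmentCost(series).cost(a, b)


def noise_scale(series: Sequence[float]) -> float:
    """Global noise standard deviation, estimated from first differences.

    σ̂ = sd(diff(y)) / √2 is insensitive to the level shifts the
    segmentation is looking for (each changepoint contaminates a single
    difference), so it estimates the *within-segment* noise — the
    constant by which the Normal change-in-mean likelihood profiles out
    the variance.  Returns 1.0 when the series is too short or exactly
    constant, leaving the series unscaled.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 2:
        return 1.0
    s = float(np.diff(y).std() / math.sqrt(2.0))
    return s if s > 0 else 1.0


@dataclass
class ChangepointResult:
    """Ordered changepoints with segment means and the penalized objective.

    ``changepoints`` are 1-based indices of the last element of each
    segment except the final one; ``objective`` is
    Σ_segments C(segment) + β·(number of changepoints).
    """

    changepoints: list[int]
    segment_means: list[float]
    objective: float
    n: int

    @property
    def n_changepoints(self) -> int:
        return len(self.changepoints)

    def segments(self) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) index pairs of the segments."""
        bounds = [0, *self.changepoints, self.n]
        return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


@dataclass(frozen=True)
class ChangepointConfig:
    """Method + penalty configuration for :func:`detect_changepoints`.

    ``penalty`` is a manual β ≥ 0 or the string ``"BIC"``, meaning
    β = 2·ln(n) (one mean parameter plus one location per changepoint).
    """

    method: str = "PELT"
    penalty: Union[float, str] = "BIC"
    max_changepoints: Optional[int] = None

    def __post_init__(self):
        if self.method.upper() not in _METHODS:
            raise ParameterError(
                f"unknown method {self.method!r}; choose from {_METHODS}"
            )
        if isinstance(self.penalty, str):
            if self.penalty.upper() != "BIC":
                raise ParameterError(f"unknown penalty rule {self.penalty!r}")
        elif self.penalty < 0:
            raise ParameterError(f"penalty must be >= 0, got {self.penalty}")
        if self.method.upper() == "BINSEG":
            if self.max_changepoints is not None and self.max_changepoints < 1:
                raise ParameterError("max_changepoints must be >= 1")

    def resolve_penalty(self, n: int) -> float:
        if isinstance(self.penalty, str):
            return 2.0 * math.log(n) if n > 1 else 0.0
        return float(self.penalty)


def _build_result(cost: SegmentCost, changepoints: list[int], beta: float) -> ChangepointResult:
    bounds = [0, *changepoints, cost.n]
    means, total = [], 0.0
    for i in range(len(bounds) - 1):
        a, b = bounds[i] + 1, bounds[i + 1]
        means.append(cost.mean(a, b))
        total += cost.cost(a, b)
    return ChangepointResult(
        changepoints=list(changepoints),
        segment_means=means,
        objective=total + beta * len(changepoints),
        n=cost.n,
    )


def _backtrack(prev: list[int], t: int) -> list[int]:
    cps = []
    while t > 0:
        s = prev[t]
        if s > 0:
            cps.append(s)
        t = s
    return cps[::-1]


def _optimal_partition(
    series: Sequence[float], beta: float, prune: bool
) -> ChangepointResult:
    """Shared DP for exact optimal partitioning and PELT."""
    if beta < 0:
        raise ParameterError(f"penalty must be >= 0, got {beta}")
    cost = SegmentCost(series)
    n = cost.n
    if n == 0:
        raise ParameterError("empty series")

    F = [0.0] * (n + 1)
    F[0] = -beta
    m = [0] * (n + 1)        # changepoints in the optimal partition of y[1..t]
    prev = [0] * (n + 1)
    candidates = [0]

    for t in range(1, n + 1):
        best_s, best_f, best_m = -1, math.inf, -1
        for s in candidates:
            f = F[s] + cost.cost(s + 1, t) + beta
            cand_m = m[s] + (1 if s > 0 else 0)
            tol = _EPS * (1.0 + abs(f) + abs(best_f if best_s >= 0 else 0.0))
            if f < best_f - tol:
                take = True
            elif f <= best_f + tol:
                if cand_m < best_m:
                    take = True
                elif cand_m == best_m:
                    # exact objective tie with equal count: smallest vector wins
                    cand_vec = _backtrack(prev, s) + ([s] if s > 0 else [])
                    best_vec = _backtrack(prev, best_s) + ([best_s] if best_s > 0 else [])
                    take = cand_vec < best_vec
                else:
                    take = False
            else:
                take = False
            if take:
                best_s, best_f, best_m = s, f, cand_m
        F[t], prev[t], m[t] = best_f, best_s, best_m

        if prune:
            tol = _EPS * (1.0 + abs(F[t]))
            candidates = [
                s for s in candidates if F[s] + cost.cost(s + 1, t) <= F[t] + tol
            ]
        candidates.append(t)

    return _build_result(cost, _backtrack(prev, n), beta)


def exact_segmentation(series: Sequence[float], beta: float) -> ChangepointResult:
    """Globally optimal penalized segmentation via optimal partitioning (O(n²))."""
    return _optimal_partition(series, beta, prune=False)


def pelt(series: Sequence[float], beta: float) -> ChangepointResult:
    """Optimal partitioning with safe pruning; identical output to
    :func:`exact_segmentation`, typically near-linear cost."""
    return _optimal_partition(series, beta, prune=True)


def _best_split(cost: SegmentCost, a: int, b: int) -> tuple[float, int]:
    """Largest cost reduction Δ and its (first-argmax) split within [a, b]."""
    if b <= a:
        return -math.inf, -1
    whole = cost.cost(a, b)
    best_delta, best_tau = -math.inf, -1
    for tau in range(a, b):
        delta = whole - cost.cost(a, tau) - cost.cost(tau + 1, b)
        if best_tau < 0 or delta > best_delta + _EPS * (1.0 + abs(best_delta)):
            best_delta, best_tau = delta, tau
    return best_delta, best_tau


def amoc(series: Sequence[float], beta: float) -> ChangepointResult:
    """At-most-one-change: accept the best single split iff its Δ > β."""
    cost = SegmentCost(series)
    if cost.n == 1:
        return _build_result(cost, [], beta)
    if cost.n < 1:
        raise ParameterError("series must have at least one element")
    delta, tau = _best_split(cost, 1, cost.n)
    cps = [tau] if delta > beta else []
    return _build_result(cost, cps, beta)


def binseg(
    series: Sequence[float], beta: float, max_changepoints: Optional[int] = None
) -> ChangepointResult:
    """Greedy binary segmentation (approximate; objective ≥ exact optimum).

    Repeatedly applies the best available single split until no split
    improves by more than β or ``max_changepoints`` is reached.
    """
    cost = SegmentCost(series)
    if cost.n == 1:
        return _build_result(cost, [], beta)
    if max_changepoints is not None and max_changepoints < 1:
        raise ParameterError("max_changepoints must be >= 1")
    cap = max_changepoints if max_changepoints is not None else cost.n - 1

    segments = [(1, cost.n)]
    cps: list[int] = []
    while len(cps) < cap:
        best = (-math.inf, -1, -1)  # (delta, tau, segment index)
        for k, (a, b) in enumerate(segments):
            delta, tau = _best_split(cost, a, b)
            if delta > best[0]:
                best = (delta, tau, k)
        delta, tau, k = best
        if delta <= beta:
            break
        a, b = segments.pop(k)
        segments[k:k] = [(a, tau), (tau + 1, b)]
        cps.append(tau)
        cps.sort()
    return _build_result(cost, cps, beta)


def detect_changepoints(
    series: Sequence[float], config: ChangepointConfig = ChangepointConfig()
) -> ChangepointResult:
    """Dispatch to the configured detector with the resolved penalty."""
    y = np.asarray(series, dtype=float)
    beta = config.resolve_penalty(len(y))
    method = config.method.upper()
    if method == "AMOC":
        return amoc(y, beta)
    if method == "BINSEG":
        return binseg(y, beta, config.max_changepoints)
    if method == "EXACT":
        return exact_segmentation(y, beta)
    return pelt(y, beta)
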