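"""Synthetic event-stream generator with planted cascades.

Each case is a piecewise-constant-rate point process over ``[0, D)``
minutes: a low baseline rate λ0 everywhere except inside zero or more
planted cascade intervals, where the rate jumps to λ1 > λ0.  Event
types are drawn from one categorical distribution outside cascades
(``p_out``) and another inside (``p_in``); optionally the first event of
every cascade is forced to a fixed trigger type.  Ground-truth intervals
and per-event labels accompany every case, so detection and enrichment
can be scored against what was planted.

Defaults emulate a multi-site robot-assisted-surgery disruption study:
41 cases, ≈48 events per case (0.2 events/min over 240 min), most cases
with at most one 5-minute cascade, and nine disruption-type codes whose
inside/outside frequencies mirror the published in-/out-of-cascade
shares (training elevated inside cascades; equipment and coordination
most common overall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import ANY_EVENT, CASE, EVENT_TYPE, IN_CASCADE, RELATIVE_TIME, TIME, EventTable
from .enrichment import EnrichmentTable, enrichment_from_counts

#: The nine disruption-type codes.
TYPE_CODES = ("COM", "COO", "EQ", "EXT", "IC", "SDM", "TRN", "ENV", "PF")

#: Baseline (outside-cascade) type frequencies.
DEFAULT_P_OUT = {
    "TRN": 0.17, "COM": 0.14, "ENV": 0.01, "SDM": 0.08, "IC": 0.06,
    "EQ": 0.24, "PF": 0.03, "COO": 0.20, "EXT": 0.07,
}

#: In-cascade type frequencies (training elevated).
DEFAULT_P_IN = {
    "TRN": 0.27, "COM": 0.15, "ENV": 0.01, "SDM": 0.07, "IC": 0.06,
    "EQ": 0.21, "PF": 0.03, "COO": 0.17, "EXT": 0.03,
}

#: Cascades-per-case distribution: 23/41 cases one cascade, 1/41 two.
DEFAULT_CASCADES_PER_CASE = {0: 17 / 41, 1: 23 / 41, 2: 1 / 41}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level generator parameters (rates in events/min, times in min)."""

    n_cases: int = 41
    case_duration: float = 240.0
    baseline_rate: float = 0.2
    cascade_rate: float = 2.0
    cascades_per_case: Union[int, dict] = field(
        default_factory=lambda: dict(DEFAULT_CASCADES_PER_CASE)
    )
    cascade_duration: float = 5.0
    p_out: dict = field(default_factory=lambda: dict(DEFAULT_P_OUT))
    p_in: dict = field(default_factory=lambda: dict(DEFAULT_P_IN))
    forced_trigger: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if not (self.cascade_rate > self.baseline_rate >= 0):
            raise ParameterError("need cascade_rate > baseline_rate >= 0")
        if self.case_duration <= 0 or self.cascade_duration <= 0:
            raise ParameterError("durations must be positive")
        for name, p in (("p_out", self.p_out), ("p_in", self.p_in)):
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ParameterError(f"{name} must sum to 1")
            if any(v < 0 for v in p.values()):
                raise ParameterError(f"{name} has negative probabilities")
        if isinstance(self.cascades_per_case, dict):
            if abs(sum(self.cascades_per_case.values()) - 1.0) > 1e-9:
                raise ParameterError("cascades_per_case distribution must sum to 1")
        max_k = (
            self.cascades_per_case
            if isinstance(self.cascades_per_case, int)
            else max(self.cascades_per_case)
        )
        if max_k * self.cascade_duration > self.case_duration:
            raise ParameterError(
                "cascade intervals cannot fit inside the case duration without overlap"
            )


@dataclass
class SyntheticCase:
    """One generated case with its ground truth."""

    case_id: object
    events: EventTable
    intervals: list[tuple[float, float]]  # planted [start, end) cascades

    @property
    def true_labels(self) -> np.ndarray:
        return self.events.df[IN_CASCADE].to_numpy(dtype=bool)


@dataclass
class SyntheticStudy:
    """A collection of cases plus pooled events and ground-truth enrichment."""

    cases: list[SyntheticCase]
    events: EventTable
    truth_enrichment: Optional[EnrichmentTable]

    @property
    def intervals(self) -> dict:
        return {c.case_id: list(c.intervals) for c in self.cases}


def _draw_n_cascades(config: SyntheticConfig, rng: np.random.Generator) -> int:
    if isinstance(config.cascades_per_case, int):
        return config.cascades_per_case
    ks = sorted(config.cascades_per_case)
    probs = np.array([config.cascades_per_case[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=probs / probs.sum()))


def _place_intervals(
    k: int, length: float, duration: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Uniformly place k non-overlapping [s, s+length) intervals in [0, duration)."""
    if k == 0:
        return []
    if k * length > duration:
        raise ParameterError("cascade intervals cannot be placed without overlap")
    for _ in range(1000):
        starts = np.sort(rng.uniform(0.0, duration - length, size=k))
        if k == 1 or np.all(np.diff(starts) >= length):
            return [(float(s), float(s + length)) for s in starts]
    raise ParameterError("failed to place non-overlapping cascade intervals")


def _sample_piece(
    rng: np.random.Generator, a: float, b: float, rate: float
) -> np.ndarray:
    """Homogeneous Poisson piece: Poisson count, then uniform placement."""
    if b <= a or rate == 0.0:
        return np.empty(0)
    n = rng.poisson(rate * (b - a))
    return np.sort(rng.uniform(a, b, size=n))


def _sample_types(
    rng: np.random.Generator, n: int, p: dict
) -> np.ndarray:
    codes = list(p)
    probs = np.array([p[c] for c in codes], dtype=float)
    return rng.choice(codes, size=n, p=probs / probs.sum())


def generate_case(
    config: SyntheticConfig, case_id, seed: int
) -> SyntheticCase:
    """Generate one case; fully reproducible from ``seed``.

    Event times come from the piecewise-constant-rate process, types
    from ``p_in`` / ``p_out`` by location; when ``forced_trigger`` is
    set, the first event of each planted interval is re-typed to it.
    """
    rng = np.random.default_rng(seed)
    k = _draw_n_cascades(config, rng)
    intervals = _place_intervals(
        k, config.cascade_duration, config.case_duration, rng
    )

    # piecewise-constant pieces: baseline between intervals, cascade inside
    pieces: list[tuple[float, float, float, bool]] = []
    cursor = 0.0
    for s, e in intervals:
        pieces.append((cursor, s, config.baseline_rate, False))
        pieces.append((s, e, config.cascade_rate, True))
        cursor = e
    pieces.append((cursor, config.case_duration, config.baseline_rate, False))

    times, types, inside = [], [], []
    for a, b, rate, is_cascade in pieces:
        t = _sample_piece(rng, a, b, rate)
        ty = _sample_types(rng, len(t), config.p_in if is_cascade else config.p_out)
        if is_cascade and config.forced_trigger is not None and len(t):
            ty[0] = config.forced_trigger
        times.append(t)
        types.append(ty)
        inside.append(np.full(len(t), is_cascade))

    t = np.concatenate(times) if times else np.empty(0)
    df = pd.DataFrame(
        {
            TIME: t,
            CASE: case_id,
            EVENT_TYPE: np.concatenate(types) if types else np.empty(0, dtype=object),
            IN_CASCADE: np.concatenate(inside) if inside else np.empty(0, dtype=bool),
        }
    )
    df = df.sort_values(TIME, kind="stable", ignore_index=True)
    df[ANY_EVENT] = 1
    # events are generated on a [0, D) case clock, so relative time IS the
    # time column; re-anchoring at the first event would shift the planted
    # intervals off the ground-truth clock
    df[RELATIVE_TIME] = df[TIME]
    return SyntheticCase(case_id=case_id, events=EventTable(df), intervals=intervals)


def case_seeds(master_seed: int, n_cases: int) -> list[int]:
    """Deterministic per-case seeds derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n_cases, dtype=np.uint32)
    return [int(s) for s in state]


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate all cases and the ground-truth pooled enrichment table."""
    seeds = case_seeds(config.seed, config.n_cases)
    cases = [
        generate_case(config, case_id=i + 1, seed=seeds[i])
        for i in range(config.n_cases)
    ]
    frames = [c.events.df for c in cases if len(c.events.df)]
    if frames:
        pooled = EventTable(pd.concat(frames, ignore_index=True))
    else:
        pooled = EventTable(
            pd.DataFrame(
                {
                    TIME: pd.Series(dtype=float),
                    CASE: pd.Series(dtype=object),
                    EVENT_TYPE: pd.Series(dtype=object),
                    IN_CASCADE: pd.Series(dtype=bool),
                    ANY_EVENT: pd.Series(dtype=int),
                    RELATIVE_TIME: pd.Series(dtype=float),
                }
            )
        )
    truth = None
    if len(pooled.df):
        counts = {
            str(et): (int(sub[IN_CASCADE].sum()), len(sub))
            for et, sub in pooled.df.groupby(EVENT_TYPE, sort=True)
        }
        truth = enrichment_from_counts(counts)
    return SyntheticStudy(cases=cases, events=pooled, truth_enrichment=truth)


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write pooled events CSV plus ground-truth intervals/labels JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = study.events.df
    df[[TIME, CASE, EVENT_TYPE]].to_csv(out / "events.csv", index=False)
    truth = {
        "intervals": {str(k): v for k, v in study.intervals.items()},
        "in_cascade": df[IN_CASCADE].astype(int).tolist(),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
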