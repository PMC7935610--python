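"""Event-type enrichment: conditional probabilities of cascade membership.

For each event type ET, with n_in in-cascade events out of n total, and
N_in / N the pooled totals over all types:

========================  =============================
P(cascade | ET)           n_in / n
P(ET)                     n / N
P(ET | cascade)           n_in / N_in
P(ET | not cascade)       (n − n_in) / (N − N_in)
========================  =============================

An "Any Event" row pools all types: N_in, N, N_in/N, 1, 1, 1.  Events
are pooled over all cases (the totals are study-wide counts, not
per-case averages).  Unrounded probabilities are retained and satisfy
Σ P(ET) = Σ P(ET|cascade) = Σ P(ET|¬cascade) = 1 and the law of total
probability exactly; displayed values are rounded half-away-from-zero
to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import EVENT_TYPE, IN_CASCADE, EventTable

ANY_EVENT_LABEL = "Any Event"

_PROB_COLS = [
    "P_cascade_given_ET",
    "P_ET",
    "P_ET_given_cascade",
    "P_ET_given_notcascade",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.125 → 0.13, −0.125 → −0.13)."""
    if x != x:  # NaN
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class EnrichmentTable:
    """Per-type counts and conditional probabilities, plus the pooled row.

    ``table`` holds unrounded probabilities, one row per event type
    sorted by P(cascade|ET) descending (count descending on ties), with
    the Any Event row last.
    """

    table: pd.DataFrame = field(repr=False)
    n_total: int = 0
    n_in_cascade: int = 0

    @property
    def rounded(self) -> pd.DataFrame:
        """Display view: probabilities rounded to 2 decimals, half away from zero."""
        out = self.table.copy()
        for col in _PROB_COLS:
            out[col] = out[col].map(lambda v: round_half_away(v, 2))
        return out

    def row(self, event_type: str) -> pd.Series:
        sel = self.table[self.table["EventType"] == event_type]
        if sel.empty:
            raise ParameterError(f"unknown event type {event_type!r}")
        return sel.iloc[0]

    def write_csv(self, path) -> None:
        self.rounded.rename(columns={"EventType": "EventType"}).to_csv(
            path, index=False
        )


def enrichment_from_counts(counts: dict[str, tuple[int, int]]) -> EnrichmentTable:
    """Build the enrichment table from per-type (n_in, n) count pairs.

    ``counts`` maps event type → (in-cascade count, total count).  This
    is the computational core of :func:`enrichment_table` and is also
    useful when only published counts, not raw events, are available.
    """
    if not counts:
        raise ParameterError("no event types supplied")
    for et, (n_in, n) in counts.items():
        if not (0 <= n_in <= n):
            raise ParameterError(
                f"type {et!r}: in-cascade count {n_in} outside [0, {n}]"
            )
    N = sum(n for _, n in counts.values())
    N_in = sum(n_in for n_in, _ in counts.values())
    if N == 0:
        raise ParameterError("zero total events")
    N_out = N - N_in

    rows = []
    for et, (n_in, n) in counts.items():
        rows.append(
            {
                "EventType": et,
                "InCascadeCount": n_in,
                "DisruptionCount": n,
                "P_cascade_given_ET": n_in / n if n else np.nan,
                "P_ET": n / N,
                "P_ET_given_cascade": n_in / N_in if N_in else np.nan,
                "P_ET_given_notcascade": (n - n_in) / N_out if N_out else np.nan,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["P_cascade_given_ET", "DisruptionCount"],
        ascending=[False, False],
        kind="stable",
        ignore_index=True,
    )
    pooled = pd.DataFrame(
        [
            {
                "EventType": ANY_EVENT_LABEL,
                "InCascadeCount": N_in,
                "DisruptionCount": N,
                "P_cascade_given_ET": N_in / N,
                "P_ET": 1.0,
                "P_ET_given_cascade": 1.0 if N_in else np.nan,
                "P_ET_given_notcascade": 1.0 if N_out else np.nan,
            }
        ]
    )
    table = pd.concat([df, pooled], ignore_index=True)
    return EnrichmentTable(table=table, n_total=N, n_in_cascade=N_in)


def enrichment_table(labeled_events: EventTable) -> EnrichmentTable:
    """Compute the enrichment table from in-cascade-labeled events.

    Requires ``EventType`` and ``InCascade`` columns (see
    :func:`cascadeflow.cascade.label_events`).
    """
    df = labeled_events.df
    if EVENT_TYPE not in df.columns:
        raise ParameterError("events carry no EventType column")
    if IN_CASCADE not in df.columns:
        raise ParameterError("events carry no InCascade labels; run label_events first")
    if len(df) == 0:
        raise ParameterError("zero total events")
    counts = {
        str(et): (int(sub[IN_CASCADE].sum()), len(sub))
        for et, sub in df.groupby(EVENT_TYPE, sort=True)
    }
    return enrichment_from_counts(counts)


def share_statements(
    table: EnrichmentTable, event_type: str
) -> tuple[int, int, int]:
    """Percent shares of one type: (of cascade events, overall, of non-cascade).

    Each is 100·P rounded to the nearest integer percent (half away from
    zero); NaN probabilities (no in-cascade events at all) report as 0.
    """
    row = table.row(event_type)

    def pct(p: float) -> int:
        return 0 if p != p else int(round_half_away(100.0 * p, 0))

    return (
        pct(row["P_ET_given_cascade"]),
        pct(row["P_ET"]),
        pct(row["P_ET_given_notcascade"]),
    )
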