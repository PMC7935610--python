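"""Event-table ingestion and canonical column derivation.

Event streams arrive as delimited text, one row per event, with a time
column that must be complete.  Loading normalizes the mapped columns to
canonical names (``Time``, ``Case``, ``EventType``), converts datetime
strings to numeric minutes, sorts rows by (case, time), and derives two
columns used throughout the pipeline:

``RelativeTime``
    minutes since the first event of the same case (or since the global
    earliest event when no case column exists);
``AnyEvent``
    the constant indicator 1, the default y-variable of event plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import LoadError

TIME = "Time"
CASE = "Case"
EVENT_TYPE = "EventType"
RELATIVE_TIME = "RelativeTime"
ANY_EVENT = "AnyEvent"
IN_CASCADE = "InCascade"

#: Canonical columns, in output order; extras follow verbatim.
_CANONICAL = (TIME, CASE, EVENT_TYPE, RELATIVE_TIME, ANY_EVENT)


@dataclass(frozen=True)
class ColumnMapping:
    """Maps user column names onto the time / case / event-type roles."""

    time_column: str = TIME
    case_column: Optional[str] = None
    event_type_column: Optional[str] = None

    def validate(self, columns) -> None:
        missing = [
            c
            for c in (self.time_column, self.case_column, self.event_type_column)
            if c is not None and c not in columns
        ]
        if missing:
            raise LoadError(
                f"mapped column(s) not found in input: {', '.join(missing)}"
            )


@dataclass
class EventTable:
    """Ordered event records with canonical and derived columns.

    The underlying :class:`pandas.DataFrame` always carries ``Time``
    (numeric minutes), ``RelativeTime`` and ``AnyEvent``; ``Case`` and
    ``EventType`` are present only when mapped.  Extra attribute columns
    are preserved verbatim.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self._check_invariants()

    def _check_invariants(self) -> None:
        if TIME not in self.df.columns:
            raise LoadError(f"event table lacks the {TIME!r} column")
        if self.df[TIME].isna().any():
            raise LoadError("event table Time column contains missing values")
        if RELATIVE_TIME in self.df.columns and len(self.df):
            if (self.df[RELATIVE_TIME] < 0).any():
                raise LoadError("negative RelativeTime encountered")

    @property
    def has_case(self) -> bool:
        return CASE in self.df.columns

    @property
    def has_event_type(self) -> bool:
        return EVENT_TYPE in self.df.columns

    @property
    def time(self) -> np.ndarray:
        return self.df[TIME].to_numpy(dtype=float)

    @property
    def relative_time(self) -> np.ndarray:
        return self.df[RELATIVE_TIME].to_numpy(dtype=float)

    def cases(self) -> list:
        """Distinct case identifiers in sorted order ([None] if no case column)."""
        if not self.has_case:
            return [None]
        return sorted(self.df[CASE].unique().tolist())

    def case_relative_times(self, case) -> np.ndarray:
        """Relative event times for one case, in table order."""
        if case is None and not self.has_case:
            return self.relative_time
        return self.df.loc[self.df[CASE] == case, RELATIVE_TIME].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "EventTable":
        return EventTable(self.df.copy())

    def write_csv(self, path) -> None:
        """Write the table as CSV with derived columns appended after extras."""
        cols = [c for c in (TIME, CASE, EVENT_TYPE) if c in self.df.columns]
        extras = [c for c in self.df.columns if c not in _CANONICAL + (IN_CASCADE,)]
        derived = [RELATIVE_TIME, ANY_EVENT]
        if IN_CASCADE in self.df.columns:
            derived.append(IN_CASCADE)
        self.df[cols + extras + derived].to_csv(path, index=False)


def _parse_time_column(raw: pd.Series) -> pd.Series:
    """Convert a raw time column to numeric minutes.

    Numeric values pass through; datetime strings become minutes since the
    earliest timestamp in the column.
    """
    na_mask = raw.isna() | (raw.astype(str).str.strip() == "")
    if na_mask.any():
        idx = int(np.flatnonzero(na_mask.to_numpy())[0])
        raise LoadError(f"missing value in time column at row {idx}")

    numeric = pd.to_numeric(raw, errors="coerce")
    if not numeric.isna().any():
        return numeric.astype(float)

    try:
        stamps = pd.to_datetime(raw, format="mixed")
    except (ValueError, TypeError):
        # pinpoint the first unparseable cell for the error message
        for i, v in enumerate(raw):
            try:
                pd.to_datetime(v)
            except (ValueError, TypeError):
                raise LoadError(
                    f"unparseable time value {v!r} at row {i}"
                ) from None
        raise LoadError("time column could not be parsed") from None
    origin = stamps.min()
    return (stamps - origin).dt.total_seconds() / 60.0


def compute_relative_time(events: EventTable) -> EventTable:
    """Recompute ``RelativeTime`` as time minus the per-case minimum.

    Without a case column the global minimum time is the anchor.  Returns a
    new table; the input is not mutated.
    """
    df = events.df.copy()
    if CASE in df.columns:
        df[RELATIVE_TIME] = df[TIME] - df.groupby(CASE, sort=False)[TIME].transform("min")
    else:
        df[RELATIVE_TIME] = df[TIME] - (df[TIME].min() if len(df) else 0.0)
    return EventTable(df)


def from_frame(
    df: pd.DataFrame, mapping: Optional[ColumnMapping] = None
) -> EventTable:
    """Build an :class:`EventTable` from an in-memory data frame.

    Applies the same normalization as :func:`load_events`: role columns are
    renamed to canonical names, the time column parsed to minutes, rows
    stably sorted by (case, time), and derived columns attached.
    """
    mapping = mapping or ColumnMapping()
    mapping.validate(df.columns)
    df = df.copy()

    renames = {mapping.time_column: TIME}
    if mapping.case_column:
        renames[mapping.case_column] = CASE
    if mapping.event_type_column:
        renames[mapping.event_type_column] = EVENT_TYPE
    df = df.rename(columns=renames)

    df[TIME] = _parse_time_column(df[TIME])

    # stable sort keeps simultaneous events in file order
    if CASE in df.columns:
        df = df.sort_values([CASE, TIME], kind="stable", ignore_index=True)
    else:
        df = df.sort_values(TIME, kind="stable", ignore_index=True)

    df[ANY_EVENT] = 1
    return compute_relative_time(EventTable(df))


def load_events(path, mapping: Optional[ColumnMapping] = None) -> EventTable:
    """Load an event table from a CSV or TSV file.

    Parameters
    ----------
    path
        Delimited text file with a header row.  ``.tsv``/``.tab`` files are
        read as tab-separated, everything else as comma-separated.
    mapping
        Column-role mapping; defaults to literal ``Time`` / ``Case`` /
        ``EventType`` names (case and event type optional: they are picked
        up automatically when present under those names).

    Raises
    ------
    LoadError
        Missing mapped column, missing time value (with row index), or an
        unparseable time string (with the offending value).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        raw = pd.read_csv(path, sep=sep)
    except FileNotFoundError:
        raise LoadError(f"no such file: {path}") from None

    if mapping is None:
        mapping = ColumnMapping(
            time_column=TIME,
            case_column=CASE if CASE in raw.columns else None,
            event_type_column=EVENT_TYPE if EVENT_TYPE in raw.columns else None,
        )
    else:
        # auto-adopt optional roles when unmapped but present under canonical names
        if mapping.case_column is None and CASE in raw.columns:
            mapping = replace(mapping, case_column=CASE)
        if mapping.event_type_column is None and EVENT_TYPE in raw.columns:
            mapping = replace(mapping, event_type_column=EVENT_TYPE)
    return from_frame(raw, mapping)
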