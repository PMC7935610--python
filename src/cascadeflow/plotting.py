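"""Static stem plots of event streams with faceting, pagination and overlays.

The core visual idiom is the event stem plot: a vertical line per event
at its (relative) time, height given by the y column (the constant
Any Event indicator by default).  Facets split the data by a column
value — one panel per value, paginated — with optional color and shape
encodings, and optional overlays of changepoint boundaries (vertical
lines) and cascade intervals (shaded bands).

Cardinality rules guard against unreadable output: a facet column may
have at most 500 unique values and a shape column at most 6; color is
unrestricted.  Every rendered image is accompanied by a serialized copy
of its :class:`PlotSpec`, from which the identical image can be
regenerated.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import ParameterError, SpecError
from .io import ANY_EVENT, RELATIVE_TIME, EventTable
from .cascade import CascadeSet
from .changepoint import ChangepointResult

MAX_FACET_LEVELS = 500
MAX_SHAPE_LEVELS = 6

_MARKERS = ["o", "s", "^", "D", "v", "P"]


@dataclass
class PlotSpec:
    """Declarative description of one event plot."""

    x: str = RELATIVE_TIME
    y: str = ANY_EVENT
    facet: Optional[str] = None
    page_size: int = 6
    color: Optional[str] = None
    shape: Optional[str] = None
    overlay_changepoints: Optional[list] = None  # x positions of boundaries
    overlay_cascades: Optional[list] = None      # (start, end) bands

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def validate_spec(spec: PlotSpec, events: EventTable) -> PlotSpec:
    """Check column existence and the facet/shape cardinality rules."""
    df = events.df
    for role, col in (("x", spec.x), ("y", spec.y), ("facet", spec.facet),
                      ("color", spec.color), ("shape", spec.shape)):
        if col is not None and col not in df.columns:
            raise SpecError(f"{role} column {col!r} not found in event table")
    if spec.page_size < 1:
        raise SpecError("page_size must be >= 1")
    if spec.facet is not None and df[spec.facet].nunique() > MAX_FACET_LEVELS:
        raise SpecError(
            f"facet column {spec.facet!r} has more than {MAX_FACET_LEVELS} unique values"
        )
    if spec.shape is not None and df[spec.shape].nunique() > MAX_SHAPE_LEVELS:
        raise SpecError(
            f"shape column {spec.shape!r} has more than {MAX_SHAPE_LEVELS} unique values"
        )
    return spec


def paginate(n_facets: int, page_size: int) -> tuple[int, list[int]]:
    """Page count and facet→page assignment (facets in sort order)."""
    if page_size < 1:
        raise SpecError("page_size must be >= 1")
    page_count = math.ceil(n_facets / page_size)
    assignment = [i // page_size for i in range(n_facets)]
    return page_count, assignment


def _facet_levels(spec: PlotSpec, events: EventTable) -> list:
    if spec.facet is None:
        return [None]
    return sorted(events.df[spec.facet].unique().tolist())


def _draw_panel(ax, sub, spec: PlotSpec, color_map, shape_map):
    x = sub[spec.x].to_numpy(dtype=float)
    y = sub[spec.y].to_numpy(dtype=float)
    if spec.color or spec.shape:
        for _, row in sub.iterrows():
            c = color_map[row[spec.color]] if spec.color else "C0"
            m = shape_map[row[spec.shape]] if spec.shape else None
            xv, yv = float(row[spec.x]), float(row[spec.y])
            ax.vlines(xv, 0.0, yv, colors=c, linewidth=0.8)
            if m is not None:
                ax.plot([xv], [yv], marker=m, color=c, markersize=3, linestyle="none")
    else:
        ax.vlines(x, 0.0, y, colors="C0", linewidth=0.8)
    if spec.overlay_changepoints:
        for xb in spec.overlay_changepoints:
            ax.axvline(xb, color="crimson", linestyle="--", linewidth=1.0)
    if spec.overlay_cascades:
        for start, end in spec.overlay_cascades:
            ax.axvspan(start, end, color="orange", alpha=0.3)


def build_figure(spec: PlotSpec, events: EventTable, page: int = 0):
    """Build the matplotlib figure for one page (data layer is testable)."""
    validate_spec(spec, events)
    levels = _facet_levels(spec, events)
    page_count, assignment = paginate(len(levels), spec.page_size)
    if page_count and not (0 <= page < page_count):
        raise ParameterError(f"page {page} out of range [0, {page_count})")

    page_levels = [lv for lv, pg in zip(levels, assignment) if pg == page]
    n_panels = max(len(page_levels), 1)
    ncols = min(n_panels, 3)
    nrows = math.ceil(n_panels / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.2 * nrows), squeeze=False, sharex=True
    )

    df = events.df
    color_map = {}
    if spec.color:
        for i, lv in enumerate(sorted(df[spec.color].unique().tolist())):
            color_map[lv] = f"C{i % 10}"
    shape_map = {}
    if spec.shape:
        for i, lv in enumerate(sorted(df[spec.shape].unique().tolist())):
            shape_map[lv] = _MARKERS[i]

    flat = axes.ravel()
    for ax in flat[n_panels:]:
        ax.set_visible(False)
    if spec.facet is None:
        _draw_panel(flat[0], df, spec, color_map, shape_map)
        flat[0].set_title("all events", fontsize=9)
    else:
        for ax, lv in zip(flat, page_levels):
            _draw_panel(ax, df[df[spec.facet] == lv], spec, color_map, shape_map)
            ax.set_title(f"{spec.facet} = {lv}", fontsize=9)
    for ax in flat[:n_panels]:
        ax.set_xlabel(spec.x, fontsize=8)
        ax.set_ylabel(spec.y, fontsize=8)
    fig.tight_layout()
    return fig


def overlay_from_results(
    spec: PlotSpec,
    changepoints: Optional[ChangepointResult] = None,
    bin_width: float = 1.0,
    cascades: Optional[CascadeSet] = None,
    case=None,
) -> PlotSpec:
    """Attach changepoint boundaries / cascade bands to a spec."""
    if changepoints is not None:
        spec.overlay_changepoints = [cp * bin_width for cp in changepoints.changepoints]
    if cascades is not None:
        ivs = (
            cascades.for_case(case)
            if case is not None
            else [iv for _, iv in cascades.all_intervals()]
        )
        spec.overlay_cascades = [(iv.start, iv.end) for iv in ivs]
    return spec


def render(spec: PlotSpec, events: EventTable, page: int, out) -> Path:
    """Render one page to an image file and write the spec alongside it.

    The sidecar ``<out>.spec.json`` lets the identical figure be
    regenerated from the same data.
    """
    fig = build_figure(spec, events, page)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120)
    plt.close(fig)
    Path(str(out) + ".spec.json").write_text(spec.to_json())
    return out
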