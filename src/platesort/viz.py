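"""Plate-grid visualization: well-wise scatter, histogram, heatmap and
comparison plots, plus correlation-matrix and dose-response figures.

Every figure family separates a testable data-preparation step (the
``prep_*`` functions, pure transformations into a :class:`PlateGridLayout`)
from a thin matplotlib rendering layer (:func:`render`).  Well-wise plots
draw 96 small panels in the 8x12 geometry of the plate, so data from the
same well line up across figures and plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .errors import PlatesortError, UnknownTraitError
from .io_copas import RawPlate
from .stats import CorrelationMatrix, DoseResponseTable
from .summarize import SummarizedPlate
from .wells import ALL_WELL_LABELS, COLUMNS, ROWS, WellID


@dataclass
class PlateGridLayout:
    """Per-well payloads addressed by well label, plus a layout kind.

    ``kind`` is one of scatter, histogram, heatmap, compare-box,
    compare-bar; the payload schema depends on the kind.  Wells absent
    from ``panels`` render as empty panels.
    """

    kind: str
    panels: dict[str, Any]
    meta: dict[str, Any] = field(default_factory=dict)

    def panel(self, well: str | WellID) -> Any:
        return self.panels.get(str(well))


def _require_trait(plate: RawPlate, trait: str) -> None:
    if trait not in plate.data.columns:
        raise UnknownTraitError(f"trait {trait!r} not in plate")


def prep_trait_scatter(plate: RawPlate, x_trait: str, y_trait: str) -> PlateGridLayout:
    """Per-well (x, y) point sets; rows missing either value are dropped."""
    _require_trait(plate, x_trait)
    _require_trait(plate, y_trait)
    panels: dict[str, Any] = {}
    sub = plate.data[["well", x_trait, y_trait]].dropna()
    for well, grp in sub.groupby("well", sort=False):
        panels[well] = (grp[x_trait].to_numpy(float), grp[y_trait].to_numpy(float))
    return PlateGridLayout("scatter", panels, {"x": x_trait, "y": y_trait})


def prep_trait_histogram(plate: RawPlate, trait: str, bins: int = 30) -> PlateGridLayout:
    """Per-well histogram counts over a bin range shared across the plate,
    so panels are visually comparable; each panel's counts sum to that
    well's non-missing count."""
    _require_trait(plate, trait)
    vals = plate.data[trait].dropna()
    if len(vals):
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = 0.0, 1.0
    edges = np.linspace(lo, hi, bins + 1)
    panels: dict[str, Any] = {}
    for well, grp in plate.data.groupby("well", sort=False):
        counts, _ = np.histogram(grp[trait].dropna().to_numpy(float), bins=edges)
        panels[well] = counts
    return PlateGridLayout("histogram", panels, {"trait": trait, "edges": edges})


def prep_heatmap(summary: SummarizedPlate, column: str = "n") -> PlateGridLayout:
    """One heat value per well, taken verbatim from a summary column;
    missing values become an explicit no-data state (NaN payload)."""
    if column not in summary.data.columns:
        raise UnknownTraitError(f"column {column!r} not in summary")
    panels = {
        row.well: float(v) if v == v else math.nan
        for row, v in zip(summary.data.itertuples(index=False), summary.data[column])
    }
    return PlateGridLayout("heatmap", panels, {"column": column})


def _box_stats(values: np.ndarray) -> dict[str, Any]:
    """Median, quartiles, 1.5*IQR whiskers and outliers of one sample."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"n": 0}
    q1, med, q3 = (float(np.quantile(v, q)) for q in (0.25, 0.5, 0.75))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {
        "n": int(v.size),
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": np.sort(outliers),
    }


def prep_compare(
    a: RawPlate | SummarizedPlate,
    b: RawPlate | SummarizedPlate,
    trait_or_column: str,
) -> PlateGridLayout:
    """Pair two plates well by well for cross-plate comparison.

    Raw plates give paired box-and-whisker statistics per well; summarized
    plates give paired bar heights (the chosen column's values).  Mixing a
    raw and a summarized plate is a type mismatch.
    """
    if isinstance(a, RawPlate) != isinstance(b, RawPlate):
        raise PlatesortError("cannot compare a raw plate with a summarized plate")
    panels: dict[str, Any] = {}
    if isinstance(a, RawPlate):
        _require_trait(a, trait_or_column)
        _require_trait(b, trait_or_column)
        ga = dict(tuple(a.data.groupby("well", sort=False)))
        gb = dict(tuple(b.data.groupby("well", sort=False)))
        for well in sorted(set(ga) | set(gb), key=lambda s: WellID.from_string(s).index):
            pa = _box_stats(ga[well][trait_or_column].to_numpy(float)) if well in ga else {"n": 0}
            pb = _box_stats(gb[well][trait_or_column].to_numpy(float)) if well in gb else {"n": 0}
            panels[well] = (pa, pb)
        return PlateGridLayout("compare-box", panels, {"trait": trait_or_column})
    for s in (a, b):
        if trait_or_column not in s.data.columns:
            raise UnknownTraitError(f"column {trait_or_column!r} not in summary")
    va = a.data.set_index("well")[trait_or_column]
    vb = b.data.set_index("well")[trait_or_column]
    for well in sorted(set(va.index) | set(vb.index), key=lambda s: WellID.from_string(s).index):
        panels[well] = (
            float(va[well]) if well in va.index else math.nan,
            float(vb[well]) if well in vb.index else math.nan,
        )
    return PlateGridLayout("compare-bar", panels, {"column": trait_or_column})


# ---------------------------------------------------------------------------
# rendering


def _plate_axes(fig):
    axes = fig.subplots(8, 12, sharex=False, sharey=False)
    for r, row in enumerate(ROWS):
        for c in COLUMNS:
            ax = axes[r][c - 1]
            ax.set_xticks([])
            ax.set_yticks([])
            if c == 1:
                ax.set_ylabel(row, rotation=0, ha="right", va="center", fontsize=8)
            if r == 0:
                ax.set_title(str(c), fontsize=8)
    return axes


def _render_grid(layout: PlateGridLayout, fig) -> None:
    axes = _plate_axes(fig)
    heat_vals = None
    if layout.kind == "heatmap":
        finite = [v for v in layout.panels.values() if v == v]
        lo = min(finite) if finite else 0.0
        hi = max(finite) if finite else 1.0
        span = (hi - lo) or 1.0
        heat_vals = (lo, span)
    for well in ALL_WELL_LABELS:
        w = WellID.from_string(well)
        ax = axes[ROWS.index(w.row)][w.column - 1]
        payload = layout.panels.get(well)
        if payload is None:
            continue
        if layout.kind == "scatter":
            ax.plot(payload[0], payload[1], ".", ms=1.5, alpha=0.6)
        elif layout.kind == "histogram":
            edges = layout.meta["edges"]
            ax.bar(edges[:-1], payload, width=np.diff(edges), align="edge")
        elif layout.kind == "heatmap":
            if payload == payload:
                lo, span = heat_vals
                ax.set_facecolor(plt.get_cmap("viridis")((payload - lo) / span))
            else:
                ax.set_facecolor("lightgray")
                ax.plot([0, 1], [0, 1], color="gray", lw=0.5)
        elif layout.kind == "compare-box":
            for i, bs in enumerate(payload):
                if bs.get("n", 0) == 0:
                    continue
                ax.bxp(
                    [
                        {
                            "med": bs["median"],
                            "q1": bs["q1"],
                            "q3": bs["q3"],
                            "whislo": bs["whisker_lo"],
                            "whishi": bs["whisker_hi"],
                            "fliers": bs["outliers"],
                        }
                    ],
                    positions=[i],
                    widths=0.6,
                    showfliers=True,
                )
        elif layout.kind == "compare-bar":
            heights = [0 if v != v else v for v in payload]
            ax.bar([0, 1], heights, color=["#1f77b4", "#ff7f0e"])


def _render_cor(matrix: CorrelationMatrix, fig) -> None:
    ax = fig.subplots()
    im = ax.imshow(matrix.values.to_numpy(float), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(matrix.values.columns)))
    ax.set_xticklabels(matrix.values.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.values.index)))
    ax.set_yticklabels(matrix.values.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{matrix.method} correlation")


def _render_dr(table: DoseResponseTable, fig) -> None:
    ax = fig.subplots()
    strains = sorted(table.groups["strain"].astype(str).unique())
    cmap = plt.get_cmap("tab10")
    for i, s in enumerate(strains):
        pts = table.points[table.points["strain"].astype(str) == s]
        grp = table.groups[table.groups["strain"].astype(str) == s].sort_values("dose")
        color = cmap(i % 10)
        ax.plot(pts["dose"], pts["value"], "o", ms=3, alpha=0.5, color=color)
        ax.plot(grp["dose"], grp["mean"], "-", color=color, label=s)
    ax.set_xlabel("dose")
    ax.set_ylabel(f"{table.statistic}_{table.trait}")
    ax.legend(fontsize=7)


def render(
    prepared: PlateGridLayout | CorrelationMatrix | DoseResponseTable,
    destination: str | Path,
    style: Mapping[str, Any] | None = None,
) -> Path:
    """Render a prepared object to PNG, SVG or PDF (by file extension).

    SVG output is deterministic: identical inputs give byte-identical
    files (hash salt and metadata date pinned).
    """
    destination = Path(destination)
    fmt = destination.suffix.lstrip(".").lower()
    if fmt not in ("png", "svg", "pdf"):
        raise ValueError(f"unsupported image format: {fmt!r}")
    rc = {"svg.hashsalt": "platesort", "figure.dpi": 100}
    if style:
        rc.update(style)
    with plt.rc_context(rc):
        fig = plt.figure(figsize=(12, 8) if isinstance(prepared, PlateGridLayout) else (7, 6))
        try:
            if isinstance(prepared, PlateGridLayout):
                _render_grid(prepared, fig)
            elif isinstance(prepared, CorrelationMatrix):
                _render_cor(prepared, fig)
            elif isinstance(prepared, DoseResponseTable):
                _render_dr(prepared, fig)
            else:
                raise TypeError(f"cannot render {type(prepared).__name__}")
            metadata = {"Date": None} if fmt == "svg" else None
            fig.savefig(destination, format=fmt, metadata=metadata)
        finally:
            plt.close(fig)
    return destination
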