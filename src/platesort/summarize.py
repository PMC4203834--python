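"""Per-length normalization, per-well summarization, well removal and
well filling.

The instrument reports *integrated* optical density and fluorescence, so
bigger objects always score higher; dividing each channel by time of
flight (the length proxy) gives per-length values comparable across object
sizes.  Summarization collapses the per-object records to one row per
well: population size ``n`` plus mean, variance, median, quantiles,
minimum and maximum for every measured and normalized channel, optionally
repeated for log-transformed channels.  Missing wells can be filled with
all-NA rows so every downstream step sees the full 8x12 geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CorruptSummaryError, InvalidMetadataError
from .io_copas import NORM_FIELDS, TRAIT_FIELDS, RawPlate
from .wells import ALL_WELL_LABELS, WellID, well_from_string

log = logging.getLogger(__name__)

#: Traits summarized per well, in output order.
SUMMARY_TRAITS = (*TRAIT_FIELDS, *NORM_FIELDS)

#: Default quantiles beyond the median, as percentages.
DEFAULT_QUANTILES = (10, 25, 75, 90)

#: Statistic name prefixes used in summary column names (``<stat>_<trait>``).
BASE_STATS = ("mean", "median", "var", "min", "max")


def stat_columns(
    traits: Sequence[str] = SUMMARY_TRAITS,
    quantiles: Sequence[int] = DEFAULT_QUANTILES,
    with_log: bool = False,
) -> list[str]:
    """All ``<stat>_<trait>`` column names for a summary."""
    stats = [*BASE_STATS, *(f"q{q}" for q in quantiles)]
    names = [f"{s}_{t}" for t in traits for s in stats]
    if with_log:
        names += [f"{s}_log_{t}" for t in traits for s in stats]
    return names


@dataclass
class SummarizedPlate:
    """One row per well: ``well``, ``strain``, ``dose``, ``n`` and the
    ``<stat>_<trait>`` columns.  At most one row per well; after
    :func:`fill_wells`, exactly 96 rows in row-major order."""

    data: pd.DataFrame
    source: str = "<memory>"
    log_exclusions: pd.DataFrame | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, data: pd.DataFrame) -> "SummarizedPlate":
        return replace(self, data=data.reset_index(drop=True))

    def trait_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("well", "strain", "dose")]


class ChannelNormalizer(BaseEstimator, TransformerMixin):
    """Stateless transformer dividing EXT and fluorescence by TOF."""

    def fit(self, X: RawPlate, y=None) -> "ChannelNormalizer":
        return self

    def transform(self, X: RawPlate) -> RawPlate:
        plate, self.zero_tof_count_ = normalize(X, return_report=True)
        return plate


def normalize(plate: RawPlate, return_report: bool = False):
    """Fill the ``norm_*`` columns with channel / TOF for every object.

    Objects with TOF = 0 get missing normalized values and are counted;
    the original integrated channels are untouched.  Satisfies
    ``norm_x * tof == x`` exactly wherever TOF > 0.
    """
    data = plate.data.copy()
    tof = data["tof"].to_numpy(float)
    positive = tof > 0
    for src, dst in (("ext", "norm_ext"), ("green", "norm_green"),
                     ("yellow", "norm_yellow"), ("red", "norm_red")):
        vals = data[src].to_numpy(float)
        out = np.full_like(vals, np.nan)
        out[positive] = vals[positive] / tof[positive]
        data[dst] = out
    zero_tof = int((~positive & np.isfinite(tof)).sum())
    if zero_tof:
        log.info("%s: %d objects with TOF=0 left unnormalized", plate.source, zero_tof)
    out_plate = plate.with_data(data)
    return (out_plate, zero_tof) if return_report else out_plate


def _well_stats(values: np.ndarray, quantiles: Sequence[int]) -> dict[str, float]:
    """Summary statistics of one well's non-missing values for one trait.

    Quantiles use linear interpolation between closest order statistics
    (numpy's default, the "type 7" convention)."""
    v = values[np.isfinite(values)]
    stats: dict[str, float] = {}
    if v.size == 0:
        for s in (*BASE_STATS, *(f"q{q}" for q in quantiles)):
            stats[s] = math.nan
        return stats
    stats["mean"] = float(v.mean())
    stats["median"] = float(np.median(v))
    stats["var"] = float(v.var(ddof=1)) if v.size >= 2 else math.nan
    stats["min"] = float(v.min())
    stats["max"] = float(v.max())
    for q in quantiles:
        stats[f"q{q}"] = float(np.quantile(v, q / 100.0))
    return stats


class PlateSummarizer(BaseEstimator, TransformerMixin):
    """Transformer collapsing a RawPlate to a SummarizedPlate.

    Parameters mirror :func:`summarize_plate`; this class exists so the
    step can sit inside an sklearn pipeline next to the filters.
    """

    def __init__(
        self,
        strains: Sequence[str] | None = None,
        with_log: bool = False,
        quantiles: Sequence[int] = DEFAULT_QUANTILES,
    ):
        self.strains = strains
        self.with_log = with_log
        self.quantiles = quantiles

    def fit(self, X: RawPlate, y=None) -> "PlateSummarizer":
        return self

    def transform(self, X: RawPlate) -> SummarizedPlate:
        return summarize_plate(
            X, strains=self.strains, with_log=self.with_log, quantiles=self.quantiles
        )


def summarize_plate(
    plate: RawPlate,
    strains: Sequence[str] | None = None,
    with_log: bool = False,
    quantiles: Sequence[int] = DEFAULT_QUANTILES,
) -> SummarizedPlate:
    """Summarize a plate by well.

    One row per well that has at least one observation.  ``n`` is the
    well's observation count; per-trait statistics skip missing values.
    With ``with_log``, the same statistics are added for the natural log of
    each trait, computed over strictly positive values only — non-positive
    values are excluded rather than shifted, and per-well exclusion counts
    are kept on ``log_exclusions``.

    ``strains``, if given, must have exactly 96 labels in row-major well
    order A1..H12 and is attached by position.
    """
    strain_map = _positional_map(strains, "strains") if strains is not None else None
    quantiles = tuple(quantiles)

    rows: list[dict] = []
    excl_rows: list[dict] = []
    grouped = plate.data.groupby("well", sort=False)
    for well, sub in grouped:
        row: dict[str, object] = {"well": well, "n": int(len(sub))}
        excl: dict[str, object] = {"well": well}
        for trait in SUMMARY_TRAITS:
            vals = sub[trait].to_numpy(float)
            for s, x in _well_stats(vals, quantiles).items():
                row[f"{s}_{trait}"] = x
            if with_log:
                finite = vals[np.isfinite(vals)]
                pos = finite[finite > 0]
                excl[f"log_{trait}"] = int(finite.size - pos.size)
                logvals = np.log(pos) if pos.size else np.array([])
                for s, x in _well_stats(logvals, quantiles).items():
                    row[f"{s}_log_{trait}"] = x
        rows.append(row)
        excl_rows.append(excl)

    if not rows:
        cols = ["well", "n"] + stat_columns(quantiles=quantiles, with_log=with_log)
        df = pd.DataFrame(columns=cols)
        if strain_map is not None:
            df.insert(1, "strain", pd.Series(dtype=object))
        return SummarizedPlate(data=df, source=plate.source)
    df = pd.DataFrame(rows)
    df["_order"] = [well_from_string(w).index for w in df["well"]]
    df = df.sort_values("_order").drop(columns="_order").reset_index(drop=True)
    if strain_map is not None:
        df.insert(1, "strain", [strain_map[w] for w in df["well"]])
    cols = ["well"] + (["strain"] if strain_map is not None else []) + ["n"]
    cols += stat_columns(quantiles=quantiles, with_log=with_log)
    df = df[cols]
    excl_df = pd.DataFrame(excl_rows) if with_log else None
    return SummarizedPlate(data=df, source=plate.source, log_exclusions=excl_df)


def _positional_map(vector: Sequence, what: str) -> dict[str, object]:
    if len(vector) != 96:
        raise InvalidMetadataError(f"{what} vector must have 96 entries, got {len(vector)}")
    return dict(zip(ALL_WELL_LABELS, vector))


def remove_wells(data, wells: Sequence[str | WellID], mode: str = "na"):
    """Blank (``na`` mode) or delete (``drop`` mode) the listed wells.

    Works on both raw and summarized plates.  In ``na`` mode the entries
    stay but every trait field becomes missing (and ``n`` for summaries);
    absent wells are a warning-level no-op.
    """
    if mode not in ("na", "drop"):
        raise ValueError(f"mode must be 'na' or 'drop', got {mode!r}")
    labels = {str(w if isinstance(w, WellID) else well_from_string(str(w))) for w in wells}
    present = set(data.data["well"])
    for missing in sorted(labels - present):
        log.warning("%s: well %s not present, nothing to remove", data.source, missing)

    df = data.data.copy()
    hit = df["well"].isin(labels)
    if mode == "drop":
        return data.with_data(df[~hit])
    if isinstance(data, SummarizedPlate):
        blank_cols = [c for c in df.columns if c not in ("well", "strain", "dose")]
    else:
        blank_cols = [c for c in df.columns if c not in ("well", "object_id", "sort_status")]
    df.loc[hit, blank_cols] = np.nan
    return data.with_data(df)


def fill_wells(summary: SummarizedPlate) -> SummarizedPlate:
    """Complete a summary to exactly 96 rows in row-major order.

    Wells absent from the input are added with every statistic (and ``n``)
    missing; existing rows are unchanged.  Raises
    :class:`CorruptSummaryError` on duplicate wells.
    """
    df = summary.data
    dupes = df["well"][df["well"].duplicated()].unique()
    if len(dupes):
        raise CorruptSummaryError(f"duplicate well entries: {', '.join(dupes)}")
    missing = [w for w in ALL_WELL_LABELS if w not in set(df["well"])]
    if missing:
        pad = pd.DataFrame({"well": missing})
        df = pd.concat([df, pad], ignore_index=True)
    df = df.copy()
    df["_order"] = [well_from_string(w).index for w in df["well"]]
    df = df.sort_values("_order").drop(columns="_order").reset_index(drop=True)
    return summary.with_data(df)


def write_summary(summary: SummarizedPlate, destination: str | Path | IO[str], sep: str = "\t") -> None:
    """Export one row per well; missing values are empty fields."""
    text = summary.data.to_csv(sep=sep, index=False, na_rep="", lineterminator="\n")
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def read_summary(source: str | Path | IO[str], sep: str = "\t") -> SummarizedPlate:
    """Read a summary exported by :func:`write_summary` ("NA" also accepted)."""
    df = pd.read_csv(source, sep=sep, na_values=["NA", ""], keep_default_na=True)
    if "well" not in df.columns:
        raise InvalidMetadataError("summary file lacks a 'well' column")
    df["well"] = [str(well_from_string(w)) for w in df["well"]]
    label = str(source) if isinstance(source, (str, Path)) else "<stream>"
    return SummarizedPlate(data=df, source=label)
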