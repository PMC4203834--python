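"""Reading and writing the COPAS/BioSorter tab-delimited per-object format.

COPAS and BioSorter large-particle flow cytometers write one tab-delimited
text line per detected object, carrying the well coordinate, the instrument's
sort decision, time of flight (TOF, a proxy for object length), integrated
extinction (EXT, optical density) and up to three integrated fluorescence
channels.  Column headers vary across firmware versions, so parsing goes
through a *dialect*: a mapping from the file's column names onto the
canonical fields.  Dialects are detected from the header via a synonym
table that users can extend.

A parsed plate is held as a :class:`RawPlate`: a pandas DataFrame with one
row per object plus source metadata and a parse report.  Malformed lines
(truncated, non-numeric, invalid well) are dropped and counted rather than
treated as fatal, because instrument files commonly end mid-line.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import EmptyPlateError, UnrecognizedFormatError
from .wells import InvalidWellError, WellID

#: Canonical per-object fields, in canonical column order.
CANONICAL_FIELDS = (
    "object_id",
    "row",
    "column",
    "sort_status",
    "tof",
    "ext",
    "green",
    "yellow",
    "red",
)

#: Fields that must be mappable for a header to be recognized.
REQUIRED_FIELDS = ("tof", "ext", "row", "column")

#: Measurement channels (nonnegative numbers; fluorescence may be absent).
TRAIT_FIELDS = ("tof", "ext", "green", "yellow", "red")

#: Per-length normalized channels, filled by :func:`platesort.summarize.normalize`.
NORM_FIELDS = ("norm_ext", "norm_green", "norm_yellow", "norm_red")

#: Canonical header written by :func:`write_plate`.
CANONICAL_HEADER = (
    "Id",
    "Row",
    "Column",
    "Status sort",
    "TOF",
    "EXT",
    "Green",
    "Yellow",
    "Red",
)

# Case-insensitive synonym table: canonical field -> accepted column names.
_SYNONYMS: dict[str, set[str]] = {
    "object_id": {"id"},
    "row": {"row"},
    "column": {"column", "col"},
    "sort_status": {"status", "status sort", "sort status"},
    "tof": {"tof"},
    "ext": {"ext", "extinction"},
    "green": {"green"},
    "yellow": {"yellow"},
    "red": {"red"},
}

_MISSING_TOKENS = {"", "na", "nan"}


def register_synonym(field_name: str, column_name: str) -> None:
    """Teach the dialect detector an extra column-name synonym.

    Lets users accommodate firmware variants without editing files, e.g.
    ``register_synonym("green", "GFP")``.
    """
    if field_name not in _SYNONYMS:
        raise KeyError(f"unknown canonical field: {field_name}")
    _SYNONYMS[field_name].add(column_name.strip().lower())


@dataclass(frozen=True)
class Dialect:
    """Mapping from a file's header columns onto canonical fields."""

    name: str
    #: canonical field -> zero-based column index in the file
    columns: Mapping[str, int]
    n_columns: int

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(self.columns)


@dataclass
class ParseReport:
    """Accounting of what happened while parsing one file."""

    n_data_lines: int = 0
    n_parsed: int = 0
    dropped_lines: list[int] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_lines)


@dataclass
class RawPlate:
    """Per-object data for one plate.

    ``data`` has one row per object with columns ``object_id``, ``well``
    (canonical label), ``sort_status``, the measurement channels, the
    ``norm_*`` columns (NaN until normalization) and ``is_bubble_prob``
    (NaN until bubble classification).
    """

    data: pd.DataFrame
    source: str = "<memory>"
    dialect: str = "canonical"
    report: ParseReport = field(default_factory=ParseReport)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def wells(self) -> list[str]:
        """Distinct well labels present, in canonical plate order."""
        present = set(self.data["well"])
        return sorted(present, key=lambda s: WellID.from_string(s).index)

    def with_data(self, data: pd.DataFrame) -> "RawPlate":
        return replace(self, data=data.reset_index(drop=True))


def empty_plate_frame() -> pd.DataFrame:
    """An empty DataFrame with the full canonical column set."""
    cols = ["object_id", "well", "sort_status", *TRAIT_FIELDS, *NORM_FIELDS, "is_bubble_prob"]
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    df["object_id"] = df["object_id"].astype(int)
    df["well"] = df["well"].astype(str)
    return df


def detect_dialect(header_line: str) -> Dialect:
    """Map a header line's column names onto canonical fields.

    Matching is case-insensitive over the synonym table.  A ``Plate``
    column, if present, is tolerated (and later checked to be constant).
    Raises :class:`UnrecognizedFormatError` naming the missing columns if
    any of TOF, EXT, Row, Column cannot be found.
    """
    names = [c.strip() for c in header_line.rstrip("\r\n").split("\t")]
    lowered = [n.lower() for n in names]
    columns: dict[str, int] = {}
    for fld, syns in _SYNONYMS.items():
        for i, n in enumerate(lowered):
            if n in syns and fld not in columns:
                columns[fld] = i
    missing = [f for f in REQUIRED_FIELDS if f not in columns]
    if missing:
        raise UnrecognizedFormatError(
            "header does not look like an instrument file; missing columns: "
            + ", ".join(missing)
        )
    if "plate" in lowered:
        columns["_plate"] = lowered.index("plate")
    name = "canonical" if names == list(CANONICAL_HEADER) else "detected"
    return Dialect(name=name, columns=columns, n_columns=len(names))


def _parse_number(token: str) -> float:
    """Parse one numeric token; blank and NA become NaN; junk raises."""
    t = token.strip()
    if t.lower() in _MISSING_TOKENS:
        return math.nan
    v = float(t)  # decimal point only; no thousands separators
    if not math.isfinite(v):
        raise ValueError(f"non-finite value {t!r}")
    return v


def parse_plate(source: str | Path | IO[str], dialect: Dialect | None = None) -> RawPlate:
    """Parse an instrument file into a :class:`RawPlate`.

    One header line, then one line per object.  Lines whose required fields
    fail to parse (bad well, non-numeric or negative TOF/EXT, truncated
    line) are dropped and recorded in the plate's parse report.
    Fluorescence channels absent from the dialect come back as NaN.

    Raises :class:`EmptyPlateError` for an empty or header-only file and
    propagates :class:`UnrecognizedFormatError` from dialect detection.
    """
    if isinstance(source, (str, Path)):
        label = str(source)
        with open(source, "r", encoding="utf-8", newline="") as fh:
            lines = fh.read().splitlines()
    else:
        label = getattr(source, "name", "<stream>")
        lines = source.read().splitlines()

    if not lines or not lines[0].strip():
        raise EmptyPlateError(f"{label}: file is empty")
    if dialect is None:
        dialect = detect_dialect(lines[0])
    cols = dialect.columns

    report = ParseReport()
    records: list[dict] = []
    plate_tokens: set[str] = set()
    seen_ids: set[int] = set()
    next_id = 1
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        report.n_data_lines += 1
        parts = line.split("\t")
        try:
            rec: dict[str, object] = {}
            max_idx = max(cols[f] for f in cols if f in cols)
            if len(parts) <= max_idx:
                raise ValueError("truncated line")
            well = WellID(
                parts[cols["row"]].strip().upper(),
                int(parts[cols["column"]].strip()),
            )
            rec["well"] = str(well)
            for fld in TRAIT_FIELDS:
                if fld in cols:
                    v = _parse_number(parts[cols[fld]])
                    if fld in ("tof", "ext") and math.isnan(v):
                        raise ValueError(f"missing {fld}")
                    if not math.isnan(v) and v < 0:
                        raise ValueError(f"negative {fld}")
                    rec[fld] = v
                else:
                    rec[fld] = math.nan
            if "sort_status" in cols:
                s = parts[cols["sort_status"]].strip()
                rec["sort_status"] = int(float(s)) if s.lower() not in _MISSING_TOKENS else 0
            else:
                rec["sort_status"] = 0
            if "object_id" in cols:
                oid = int(float(parts[cols["object_id"]].strip()))
            else:
                oid = next_id
            if oid in seen_ids:
                raise ValueError(f"duplicate object id {oid}")
            if "_plate" in cols:
                plate_tokens.add(parts[cols["_plate"]].strip())
            rec["object_id"] = oid
        except (ValueError, IndexError, InvalidWellError):
            report.dropped_lines.append(lineno)
            continue
        seen_ids.add(oid)
        next_id = max(next_id, oid + 1)
        records.append(rec)
        report.n_parsed += 1

    if len(plate_tokens) > 1:
        raise UnrecognizedFormatError(
            f"{label}: multiple plate identifiers in one file: {sorted(plate_tokens)}"
        )
    if not records:
        raise EmptyPlateError(f"{label}: no parseable object records")

    df = pd.DataFrame.from_records(records)
    for fld in NORM_FIELDS:
        df[fld] = np.nan
    df["is_bubble_prob"] = np.nan
    order = ["object_id", "well", "sort_status", *TRAIT_FIELDS, *NORM_FIELDS, "is_bubble_prob"]
    return RawPlate(data=df[order], source=label, dialect=dialect.name, report=report)


def _format_value(v: object) -> str:
    if v is None:
        return ""
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    f = float(v)
    if math.isnan(f):
        return ""
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)  # shortest round-trip representation


def write_plate(plate: RawPlate, destination: str | Path | IO[str]) -> None:
    """Write a plate in the canonical dialect (LF line endings, UTF-8).

    Missing values are written as empty fields.  Floats use the shortest
    round-trip decimal form, so write -> parse preserves every canonical
    field (integers exactly, floats bit-for-bit in practice).
    """
    buf = io.StringIO()
    buf.write("\t".join(CANONICAL_HEADER) + "\n")
    for rec in plate.data.itertuples(index=False):
        w = WellID.from_string(rec.well)
        fields_out = [
            str(int(rec.object_id)),
            w.row,
            str(w.column),
            str(int(rec.sort_status)),
            _format_value(rec.tof),
            _format_value(rec.ext),
            _format_value(rec.green),
            _format_value(rec.yellow),
            _format_value(rec.red),
        ]
        buf.write("\t".join(fields_out) + "\n")
    text = buf.getvalue()
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
    else:
        destination.write(text)


def plate_from_records(records: Iterable[Mapping[str, object]], source: str = "<memory>") -> RawPlate:
    """Build a RawPlate from dicts with at least well, tof, ext.

    Convenience constructor used by the fixture generator and tests;
    assigns sequential object ids when absent.
    """
    rows = []
    for i, r in enumerate(records, start=1):
        rec = {
            "object_id": int(r.get("object_id", i)),
            "well": str(WellID.from_string(str(r["well"]))),
            "sort_status": int(r.get("sort_status", 0)),
        }
        for fld in TRAIT_FIELDS:
            rec[fld] = float(r.get(fld, math.nan))
        rows.append(rec)
    if not rows:
        return RawPlate(data=empty_plate_frame(), source=source)
    df = pd.DataFrame.from_records(rows)
    for fld in NORM_FIELDS:
        df[fld] = np.nan
    df["is_bubble_prob"] = np.nan
    order = ["object_id", "well", "sort_status", *TRAIT_FIELDS, *NORM_FIELDS, "is_bubble_prob"]
    return RawPlate(data=df[order], source=source)
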