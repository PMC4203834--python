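"""Well coordinates for a standard 96-well microtiter plate.

Rows are letters A-H, columns are integers 1-12.  The canonical string form
is the unpadded uppercase label ("A1" ... "H12") and the canonical ordering
is row-major: A1 < A2 < ... < A12 < B1 < ... < H12.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))

_WELL_RE = re.compile(r"^([A-Ha-h])(0?[1-9]|1[0-2])$")


class InvalidWellError(ValueError):
    """Raised for labels that do not name a well of a 96-well plate."""


@total_ordering
@dataclass(frozen=True)
class WellID:
    """One well of an 8x12 plate: row letter A-H, column 1-12."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS or self.column not in COLUMNS:
            raise InvalidWellError(f"not a 96-well coordinate: {self.row}{self.column}")

    @classmethod
    def from_string(cls, label: str) -> "WellID":
        m = _WELL_RE.match(label.strip()) if isinstance(label, str) else None
        if m is None:
            raise InvalidWellError(f"invalid well label: {label!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"

    @property
    def index(self) -> int:
        """Row-major position on the plate, 0 (A1) to 95 (H12)."""
        return ROWS.index(self.row) * 12 + (self.column - 1)

    def __lt__(self, other: "WellID") -> bool:
        if not isinstance(other, WellID):
            return NotImplemented
        return self.index < other.index

    def is_edge(self, depth: int = 1) -> bool:
        """True if the well lies within ``depth`` rings of the plate border."""
        r = ROWS.index(self.row)
        c = self.column - 1
        ring = min(r, 7 - r, c, 11 - c)
        return ring < depth


#: All 96 wells in row-major (canonical) order.
ALL_WELLS: tuple[WellID, ...] = tuple(
    WellID(r, c) for r in ROWS for c in COLUMNS
)

ALL_WELL_LABELS: tuple[str, ...] = tuple(str(w) for w in ALL_WELLS)


def well_from_string(label: str) -> WellID:
    """Parse a well label, tolerating lowercase and zero padding ("a01" -> A1)."""
    return WellID.from_string(label)


def well_to_string(well: WellID) -> str:
    """Canonical unpadded uppercase label of a well."""
    return str(well)


def edge_center_partition(depth: int = 1) -> tuple[list[WellID], list[WellID]]:
    """Split the plate into edge and center wells.

    With ``depth=1`` the edge is the outermost ring: rows A and H plus
    columns 1 and 12 of rows B-G, 36 wells; the remaining 60 are center.
    """
    if depth not in (1, 2):
        raise ValueError("edge depth must be 1 or 2")
    edge = [w for w in ALL_WELLS if w.is_edge(depth)]
    center = [w for w in ALL_WELLS if not w.is_edge(depth)]
    return edge, center
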