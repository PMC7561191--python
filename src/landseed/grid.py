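"""Core data model for categorical land-use rasters and county bookkeeping.

The landscape is a single-band categorical raster of five land-use classes
(Developed, Forest, Agriculture, Water, Other) plus a Background code for
cells outside the study area.  Counties partition the non-background cells;
each county carries a ledger of gross transition quotas — the number of
cells required to convert from a donor class to a target class within one
time step — which the allocator decrements as it converts cells.

Conventions shared by every module:

* cell coordinates are 0-based ``(row, col)``, row 0 at the top;
* windows are half-open in array terms, symmetric around a center cell;
* quotas are counted in cells (see :func:`hectares_to_cells`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClassCode",
    "TransitionKey",
    "LandUseGrid",
    "CountyPartition",
    "QuotaLedger",
    "ALLOWED_MATRIX",
    "ALLOWED_TRANSITIONS",
    "is_allowed",
    "allowed_targets",
    "allowed_cross_transitions",
    "hectares_to_cells",
    "build_quota_ledgers",
    "load_grid",
    "write_grid",
    "read_quota_table",
]


class ClassCode(IntEnum):
    """Land-use class codes.  BACKGROUND marks cells outside the study area."""

    BACKGROUND = 0
    DEVELOPED = 1
    FOREST = 2
    AGRICULTURE = 3
    WATER = 4
    OTHER = 5

    @property
    def letter(self) -> str:
        return _CODE_TO_LETTER[self]

    @classmethod
    def from_letter(cls, letter: str) -> "ClassCode":
        try:
            return _LETTER_TO_CODE[letter.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown land-use class letter: {letter!r}") from None


_CODE_TO_LETTER = {
    ClassCode.BACKGROUND: "bg",
    ClassCode.DEVELOPED: "d",
    ClassCode.FOREST: "f",
    ClassCode.AGRICULTURE: "a",
    ClassCode.WATER: "w",
    ClassCode.OTHER: "o",
}
_LETTER_TO_CODE = {v: k for k, v in _CODE_TO_LETTER.items()}

#: The five real (non-background) classes.
REAL_CLASSES = (
    ClassCode.DEVELOPED,
    ClassCode.FOREST,
    ClassCode.AGRICULTURE,
    ClassCode.WATER,
    ClassCode.OTHER,
)

#: Classes that may donate cells to a different class.
DONOR_CLASSES = (ClassCode.FOREST, ClassCode.AGRICULTURE, ClassCode.OTHER)


@dataclass(frozen=True, order=True)
class TransitionKey:
    """A (donor, target) pair of land-use classes."""

    donor: ClassCode
    target: ClassCode

    def __str__(self) -> str:  # e.g. "f>d"
        return f"{self.donor.letter}>{self.target.letter}"

    @classmethod
    def parse(cls, text: str) -> "TransitionKey":
        donor, _, target = text.partition(">")
        return cls(ClassCode.from_letter(donor), ClassCode.from_letter(target))

    @property
    def is_self(self) -> bool:
        return self.donor == self.target


def _build_allowed_matrix() -> np.ndarray:
    """Allowed-transition table.

    Developed never donates; Water maps only to Water; no class converts into
    Water.  Forest, Agriculture and Other may move among themselves and into
    Developed.  Self-transitions are allowed for all five classes.
    """
    m = np.zeros((6, 6), dtype=bool)
    for c in REAL_CLASSES:
        m[c, c] = True
    for donor in DONOR_CLASSES:
        for target in (ClassCode.DEVELOPED,) + DONOR_CLASSES:
            m[donor, target] = True
    return m


ALLOWED_MATRIX = _build_allowed_matrix()
ALLOWED_MATRIX.setflags(write=False)

ALLOWED_TRANSITIONS = tuple(
    TransitionKey(d, t)
    for d in REAL_CLASSES
    for t in REAL_CLASSES
    if ALLOWED_MATRIX[d, t]
)


def is_allowed(key: TransitionKey) -> bool:
    """Whether a (donor, target) transition is permitted.

    Raises ``ValueError`` for background codes: background cells are outside
    the study area and can be neither donor nor target.
    """
    if key.donor == ClassCode.BACKGROUND or key.target == ClassCode.BACKGROUND:
        raise ValueError("background is never a donor nor a target class")
    return bool(ALLOWED_MATRIX[key.donor, key.target])


def allowed_targets(donor: ClassCode) -> tuple[ClassCode, ...]:
    """Classes a donor may convert into, excluding the self-transition."""
    return tuple(
        t for t in REAL_CLASSES if t != donor and ALLOWED_MATRIX[donor, t]
    )


def allowed_cross_transitions() -> tuple[TransitionKey, ...]:
    """All allowed transitions with donor != target."""
    return tuple(k for k in ALLOWED_TRANSITIONS if not k.is_self)


def hectares_to_cells(hectares: float, cell_size: float = 90.0) -> int:
    """Convert an area in hectares to a cell count, rounding half up.

    One cell covers ``cell_size**2`` square meters, i.e.
    ``cell_size**2 / 10_000`` hectares (0.81 ha for 90 m cells).
    """
    cells = hectares * 10_000.0 / (cell_size * cell_size)
    return int(np.floor(cells + 0.5))


@dataclass
class LandUseGrid:
    """A categorical land-use raster.

    Parameters
    ----------
    values
        2-D integer array of :class:`ClassCode` values.  Background cells
        must carry ``ClassCode.BACKGROUND``.
    cell_size
        Cell edge length in meters (default 90).
    origin
        (x, y) of the upper-left corner in projected map units.
    """

    values: np.ndarray
    cell_size: float = 90.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        valid = set(int(c) for c in ClassCode)
        present = set(np.unique(self.values).tolist())
        bad = present - valid
        if bad:
            raise ValueError(f"unknown class value(s) in grid: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def background_mask(self) -> np.ndarray:
        return self.values == ClassCode.BACKGROUND

    def class_counts(self) -> dict[ClassCode, int]:
        """Cell count per class, background included."""
        return {c: int(np.sum(self.values == c)) for c in ClassCode}

    def cell_area_ha(self) -> float:
        return self.cell_size * self.cell_size / 10_000.0

    def copy(self) -> "LandUseGrid":
        return LandUseGrid(self.values.copy(), self.cell_size, self.origin)


@dataclass
class CountyPartition:
    """County labels aligned to a grid, with optional grouping/region maps.

    Every non-background cell belongs to exactly one county; label 0 is
    reserved for background.
    """

    labels: np.ndarray
    grouping_of: dict[int, int] = field(default_factory=dict)
    region_of: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)

    @property
    def county_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def mask(self, county_id: int) -> np.ndarray:
        return self.labels == county_id

    def validate_against(self, grid: LandUseGrid) -> None:
        if self.labels.shape != grid.shape:
            raise ValueError("county partition shape does not match grid")
        uncovered = (~grid.background_mask) & (self.labels == 0)
        if uncovered.any():
            raise ValueError(
                f"{int(uncovered.sum())} non-background cells lack a county"
            )

    def grouping(self, county_id: int) -> int:
        return self.grouping_of.get(county_id, 0)

    def region(self, county_id: int) -> int:
        return self.region_of.get(county_id, 0)


class QuotaLedger:
    """Remaining gross transition quotas for one county, in cells.

    The ledger tracks, per allowed cross transition, the initial quota, the
    remaining quota and the shortfall recorded when a target class is
    abandoned.  The accounting identity ``converted + remaining == initial``
    holds at all times, and ``converted + shortfall == initial`` once
    allocation for the county has terminated.
    """

    def __init__(self, county_id: int, quotas: Mapping[TransitionKey, int]):
        self.county_id = county_id
        self.initial: dict[TransitionKey, int] = {}
        for key, cells in quotas.items():
            if key.is_self:
                continue
            if not is_allowed(key):
                raise ValueError(f"disallowed transition {key} in quota table")
            if cells < 0 or int(cells) != cells:
                raise ValueError(f"quota for {key} must be a non-negative integer")
            self.initial[key] = int(cells)
        self.remaining: dict[TransitionKey, int] = dict(self.initial)
        self.shortfall: dict[TransitionKey, int] = {k: 0 for k in self.initial}

    def converted(self, key: TransitionKey) -> int:
        return self.initial.get(key, 0) - self.remaining.get(key, 0)

    def remaining_to(self, target: ClassCode) -> int:
        """Total remaining quota into a target class, summed over donors."""
        return sum(v for k, v in self.remaining.items() if k.target == target)

    def decrement(self, key: TransitionKey) -> None:
        if self.remaining.get(key, 0) <= 0:
            raise ValueError(f"quota for {key} already exhausted")
        self.remaining[key] -= 1

    def record_shortfall(self, target: ClassCode) -> None:
        """Move all remaining quota into ``target`` to the shortfall column."""
        for key in self.remaining:
            if key.target == target and self.remaining[key] > 0:
                self.shortfall[key] += self.remaining[key]

    def targets(self) -> list[ClassCode]:
        return sorted({k.target for k in self.initial}, key=int)

    def total_initial(self) -> int:
        return sum(self.initial.values())

    def copy(self) -> "QuotaLedger":
        dup = QuotaLedger(self.county_id, self.initial)
        dup.remaining = dict(self.remaining)
        dup.shortfall = dict(self.shortfall)
        return dup


def build_quota_ledgers(table: pd.DataFrame) -> dict[int, QuotaLedger]:
    """Build per-county quota ledgers from a long-format table.

    ``table`` needs columns ``county, donor, target, cells`` with donor and
    target as class letters (d/f/a/w/o).  Self-transition rows are accepted
    but ignored with a log note — they consume no allocation.  Disallowed
    pairs raise a ``ValueError`` listing the offending rows.
    """
    required = {"county", "donor", "target", "cells"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"quota table missing columns: {sorted(missing)}")

    bad_rows = []
    ledgers: dict[int, dict[TransitionKey, int]] = {}
    for idx, row in table.iterrows():
        key = TransitionKey(
            ClassCode.from_letter(str(row["donor"])),
            ClassCode.from_letter(str(row["target"])),
        )
        if key.is_self:
            logger.info("ignoring self-transition quota row %s (%s)", idx, key)
            continue
        if not is_allowed(key):
            bad_rows.append((idx, str(key)))
            continue
        county = int(row["county"])
        ledgers.setdefault(county, {})
        ledgers[county][key] = ledgers[county].get(key, 0) + int(row["cells"])
    if bad_rows:
        raise ValueError(f"disallowed transitions in quota table rows: {bad_rows}")
    return {c: QuotaLedger(c, q) for c, q in ledgers.items()}


def read_quota_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"donor": str, "target": str})


# ---------------------------------------------------------------------------
# Raster I/O — plain-text ESRI ASCII grid.


def write_grid(grid: LandUseGrid | np.ndarray, path: str | Path,
               cell_size: float = 90.0, origin: tuple[float, float] = (0.0, 0.0),
               nodata: int = -9999) -> None:
    """Write an integer raster as an ESRI ASCII grid.

    Background cells are written as the nodata value so that a round trip
    through :func:`load_grid` reproduces the grid exactly.
    """
    if isinstance(grid, LandUseGrid):
        values = grid.values
        cell_size = grid.cell_size
        origin = grid.origin
        out = np.where(values == ClassCode.BACKGROUND, nodata, values)
    else:
        out = np.asarray(grid)
    rows, cols = out.shape
    yll = origin[1] - rows * cell_size  # ASCII grids anchor at the lower-left
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {origin[0]}\n"
        f"yllcorner {yll}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%d")


def load_grid(path: str | Path) -> LandUseGrid:
    """Read a categorical land-use raster from an ESRI ASCII grid file.

    Nodata cells map to :attr:`ClassCode.BACKGROUND`; any other value not in
    the class legend raises a format error naming the offending value.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, dtype=np.int64, ndmin=2)
    nodata = int(header.get("nodata_value", -9999))
    cell_size = float(header.get("cellsize", 90.0))
    rows = int(header.get("nrows", data.shape[0]))
    xll = float(header.get("xllcorner", 0.0))
    yll = float(header.get("yllcorner", 0.0))
    origin = (xll, yll + rows * cell_size)

    values = np.where(data == nodata, int(ClassCode.BACKGROUND), data)
    legal = set(int(c) for c in ClassCode)
    bad = set(np.unique(values).tolist()) - legal
    if bad:
        raise ValueError(
            f"{path.name}: raster contains value(s) {sorted(bad)} not in the "
            f"land-use class legend {sorted(legal)}"
        )
    return LandUseGrid(values, cell_size=cell_size, origin=origin)
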