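"""Tucson decadal (.rwl) ring-width I/O and climate/chronology CSV tables.

The Tucson decadal layout stores one measurement series as a block of
lines.  Each line carries the series id, the calendar year of its first
value and up to ten integer measurements; the series ends with a
terminator whose value encodes the measurement precision:

* ``999``   -- values are hundredths of a millimetre (0.01 mm)
* ``-9999`` -- values are thousandths of a millimetre (0.001 mm)

Values are converted to millimetres on read.  Missing rings are encoded
as ``0`` and kept as ``0.0`` mm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WoodComponent",
    "ClimateVariable",
    "RingWidthSeries",
    "SeriesCollection",
    "ClimateTable",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_climate_csv",
    "write_climate_csv",
    "write_chronology_csv",
    "read_chronology_csv",
    "MONTH_COLUMNS",
]

MONTH_COLUMNS = [
    "jan", "feb", "mar", "apr", "may", "jun",
    "jul", "aug", "sep", "oct", "nov", "dec",
]

#: terminator value -> measurement unit in mm
_PRECISION_BY_TERMINATOR = {999: 0.01, -9999: 0.001}
_TERMINATOR_BY_PRECISION = {0.01: 999, 0.001: -9999}


class WoodComponent(str, Enum):
    TOTAL = "TOTAL"
    EARLYWOOD = "EARLYWOOD"
    LATEWOOD = "LATEWOOD"


class ClimateVariable(str, Enum):
    Prec = "Prec"
    EvT = "EvT"
    Tmax = "Tmax"
    Tmin = "Tmin"
    PDSI = "PDSI"
    SPEI6 = "SPEI6"


#: canonical units per climate variable
CLIMATE_UNITS = {
    ClimateVariable.Prec: "mm",
    ClimateVariable.EvT: "mm",
    ClimateVariable.Tmax: "degC",
    ClimateVariable.Tmin: "degC",
    ClimateVariable.PDSI: "unitless",
    ClimateVariable.SPEI6: "unitless",
}


class RwlParseError(ValueError):
    """Raised for malformed .rwl content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class RingWidthSeries:
    """One tree/core measurement series in millimetres."""

    series_id: str
    first_year: int
    values: np.ndarray
    component: WoodComponent = WoodComponent.TOTAL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError(f"series {self.series_id!r}: values must be a non-empty 1-d array")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError(f"series {self.series_id!r}: ring widths must be finite and >= 0")
        self.component = WoodComponent(self.component)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SeriesCollection:
    """A set of same-component series for one site/species."""

    series: list[RingWidthSeries]
    site_id: str = ""
    species: str = ""
    component: WoodComponent = WoodComponent.TOTAL

    def __post_init__(self) -> None:
        self.component = WoodComponent(self.component)
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate series ids: {dupes}")
        for s in self.series:
            if s.component != self.component:
                raise ValueError(
                    f"series {s.series_id!r} component {s.component.value} != "
                    f"collection component {self.component.value}"
                )

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def year_span(self) -> tuple[int, int]:
        return (min(s.first_year for s in self.series),
                max(s.last_year for s in self.series))


@dataclass
class ClimateTable:
    """Monthly climate matrix (years x 12, Jan..Dec), NaN for missing."""

    variable: ClimateVariable
    first_year: int
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.variable = ClimateVariable(self.variable)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 12:
            raise ValueError("climate values must be an (n_years, 12) matrix")
        if not self.units:
            self.units = CLIMATE_UNITS[self.variable]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.values))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.values) - 1

    def value(self, year: int, month: int) -> float:
        """Monthly value; month is 1..12; NaN when year outside the table."""
        if not 1 <= month <= 12:
            raise ValueError(f"month must be 1..12, got {month}")
        if not self.first_year <= year <= self.last_year:
            return float("nan")
        return float(self.values[year - self.first_year, month - 1])


# ---------------------------------------------------------------------------
# Tucson .rwl

def read_rwl(
    path: str | Path,
    component: WoodComponent = WoodComponent.TOTAL,
    precision: float | None = None,
) -> SeriesCollection:
    """Read a Tucson decadal .rwl file.

    Precision is detected from the series terminator (999 -> 0.01 mm,
    -9999 -> 0.001 mm); pass ``precision`` to override for files that do
    not follow the terminator convention.
    """
    path = Path(path)
    text = path.read_text()

    order: list[str] = []
    values: dict[str, list[int]] = {}
    first_year: dict[str, int] = {}
    next_year: dict[str, int] = {}
    last_block_start: dict[str, int] = {}

    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        tokens = raw.split()
        if len(tokens) < 2:
            raise RwlParseError("expected series id, year and values", lineno)
        sid = tokens[0]
        if len(sid) > 8:
            raise RwlParseError(f"series id {sid!r} longer than 8 characters", lineno)
        try:
            year = int(tokens[1])
        except ValueError:
            raise RwlParseError(f"decade year {tokens[1]!r} is not an integer", lineno) from None

        if sid not in values:
            order.append(sid)
            values[sid] = []
            first_year[sid] = year
            next_year[sid] = year
        else:
            if values[sid] and values[sid][-1] == -9999:
                raise RwlParseError(f"duplicate series id {sid!r}", lineno)
            if year < last_block_start[sid]:
                raise RwlParseError(
                    f"series {sid!r}: duplicate series id or non-monotone "
                    f"decade year {year}", lineno)
            if year != next_year[sid]:
                raise RwlParseError(
                    f"series {sid!r}: decade year {year} does not follow "
                    f"previous block (expected {next_year[sid]})",
                    lineno,
                )
        last_block_start[sid] = year

        for tok in tokens[2:]:
            try:
                v = int(tok)
            except ValueError:
                raise RwlParseError(f"value {tok!r} is not an integer", lineno) from None
            if v < 0 and v != -9999:
                raise RwlParseError(f"negative ring width {v}", lineno)
            values[sid].append(v)
            next_year[sid] += 1

    if not order:
        raise RwlParseError("no series found in file")

    series = []
    for sid in order:
        vals = values[sid]
        # -9999 is always a terminator; 999 terminates only in last position
        # (it is a valid 0.999 mm measurement in thousandth-mm files)
        unit = precision
        if vals and vals[-1] in _PRECISION_BY_TERMINATOR:
            if unit is None:
                unit = _PRECISION_BY_TERMINATOR[vals[-1]]
            vals = vals[:-1]
        elif unit is None:
            raise RwlParseError(
                f"series {sid!r} has no terminator (999 or -9999); "
                "pass an explicit precision to read it"
            )
        if any(v == -9999 for v in vals):
            raise RwlParseError(f"series {sid!r}: -9999 terminator before end of series")
        if not vals:
            raise RwlParseError(f"series {sid!r} has no values")
        series.append(
            RingWidthSeries(
                series_id=sid,
                first_year=first_year[sid],
                values=np.array(vals, dtype=float) * unit,
                component=component,
            )
        )
    return SeriesCollection(series=series, site_id=path.stem, component=component)


def write_rwl(
    collection: SeriesCollection | Iterable[RingWidthSeries],
    path: str | Path,
    precision: float = 0.001,
) -> Path:
    """Write series in Tucson decadal layout.

    ``precision`` must be 0.01 or 0.001 mm; the matching terminator (999
    or -9999) is appended to each series.  ``read_rwl(write_rwl(c))``
    is the identity on ids, years and values.
    """
    if precision not in _TERMINATOR_BY_PRECISION:
        raise ValueError("precision must be 0.01 or 0.001 (mm)")
    terminator = _TERMINATOR_BY_PRECISION[precision]
    series = list(collection)
    lines: list[str] = []
    for s in series:
        if len(s.series_id) > 8:
            raise ValueError(f"series id {s.series_id!r} longer than 8 characters")
        ints = np.rint(s.values / precision).astype(int)
        if np.any(ints < 0):
            raise ValueError(f"series {s.series_id!r}: negative ring width")
        if np.any(ints > 99999):
            raise ValueError(
                f"series {s.series_id!r}: value too large to encode at precision {precision}"
            )
        fields = [str(v) for v in ints] + [str(terminator)]
        i = 0
        while i < len(fields):
            year = s.first_year + i
            # each line runs to the end of its decade
            n_slots = 10 - (year % 10)
            chunk = fields[i:i + n_slots]
            lines.append(
                f"{s.series_id:<8}{year:>4}" + "".join(f"{f:>6}" for f in chunk)
            )
            i += len(chunk)
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# climate CSV (header: year,jan,...,dec)

def read_climate_csv(path: str | Path, variable: ClimateVariable | str) -> ClimateTable:
    """Read a year x 12 monthly climate CSV into a contiguous table.

    Years absent from the file become all-NaN rows; empty cells become
    NaN (never zero).  Rows are sorted by year on load.
    """
    variable = ClimateVariable(variable)
    path = Path(path)
    rows: dict[int, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty climate CSV")
        cols = [h.strip().lower() for h in header]
        if cols[:1] != ["year"] or cols[1:13] != MONTH_COLUMNS:
            raise ValueError(
                f"{path}: expected header 'year,{','.join(MONTH_COLUMNS)}', got {header}"
            )
        for rowno, row in enumerate(reader, start=2):
            if not any(cell.strip() for cell in row):
                continue
            if len(row) < 13:
                raise ValueError(f"{path}: row {rowno}: expected 13 columns, got {len(row)}")
            try:
                year = int(row[0])
            except ValueError:
                raise ValueError(f"{path}: row {rowno}, column 'year': non-numeric {row[0]!r}") from None
            if year in rows:
                raise ValueError(f"{path}: duplicate year {year} at row {rowno}")
            monthly = []
            for j, cell in enumerate(row[1:13]):
                cell = cell.strip()
                if cell == "" or cell.upper() in {"NA", "NAN"}:
                    monthly.append(float("nan"))
                    continue
                try:
                    monthly.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: row {rowno}, column {MONTH_COLUMNS[j]!r}: non-numeric {cell!r}"
                    ) from None
            rows[year] = monthly
    if not rows:
        raise ValueError(f"{path}: no data rows")
    years = sorted(rows)
    first, last = years[0], years[-1]
    mat = np.full((last - first + 1, 12), np.nan)
    for y, monthly in rows.items():
        mat[y - first] = monthly
    return ClimateTable(variable=variable, first_year=first, values=mat)


def write_climate_csv(table: ClimateTable, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year"] + MONTH_COLUMNS)
        for i, year in enumerate(table.years):
            row = [str(int(year))]
            for v in table.values[i]:
                row.append("" if np.isnan(v) else format(float(v), "g"))
            writer.writerow(row)
    return path


# ---------------------------------------------------------------------------
# chronology CSV (header: year,index,sample_depth)

def write_chronology_csv(years: Sequence[int], index: Sequence[float],
                         sample_depth: Sequence[int], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "index", "sample_depth"])
        for y, x, d in zip(years, index, sample_depth):
            writer.writerow([int(y), repr(float(x)), int(d)])
    return path


def read_chronology_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (years, index, sample_depth) arrays from a chronology CSV."""
    path = Path(path)
    years, index, depth = [], [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "year" not in reader.fieldnames or "index" not in reader.fieldnames:
            raise ValueError(f"{path}: expected header with 'year' and 'index'")
        for row in reader:
            years.append(int(row["year"]))
            index.append(float(row["index"]))
            depth.append(int(row.get("sample_depth", 1) or 1))
    return np.array(years), np.array(index), np.array(depth)
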