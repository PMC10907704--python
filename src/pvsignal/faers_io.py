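"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS quarterly data are distributed as dollar-delimited text files, one per
table (DEMO, DRUG, REAC, OUTC, THER, INDI), with a header line naming the
columns and one record per line.  The dialect has no quoting or escaping: an
embedded ``$`` in free text is a delimiter, full stop.  Files are Latin-1 by
default, as distributed.

This module parses those files into plain field-maps (``dict`` of column name
to string), preserving field text verbatim, and writes them back so that a
write/read round trip is the identity on field values.  Dates in FAERS are
variably precise (``YYYY``, ``YYYYMM`` or ``YYYYMMDD``) and are represented by
:class:`PartialDate` rather than being coerced to a default day or month.
"""

from __future__ import annotations

import calendar
import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "TABLE_KINDS",
    "FaersParseError",
    "PartialDate",
    "RawTableBundle",
    "parse_partial_date",
    "read_faers_table",
    "write_faers_table",
    "read_bundle",
    "write_bundle",
]

#: The six table kinds of a modern FAERS quarter.
TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")

#: Every table must carry the report key column.
MANDATORY_KEY = "PRIMARYID"

DELIMITER = "$"
DEFAULT_ENCODING = "latin-1"


class FaersParseError(ValueError):
    """Raised when a FAERS table cannot be parsed.

    Carries the offending file and, for per-line failures, the 1-based line
    number so malformed records can be located in the source file.
    """

    def __init__(self, message: str, *, path: str | Path | None = None,
                 line_number: int | None = None):
        self.path = str(path) if path is not None else None
        self.line_number = line_number
        prefix = ""
        if self.path is not None:
            prefix += f"{self.path}: "
        if line_number is not None:
            prefix += f"line {line_number}: "
        super().__init__(prefix + message)


@dataclass(frozen=True, order=True)
class PartialDate:
    """A date of which only a prefix (year, year-month) may be known.

    Invariant: ``day`` present implies ``month`` present implies ``year``
    present.  ``raw_text`` always retains the original field text, so nothing
    is lost when a value fails to parse.
    """

    year: int | None = None
    month: int | None = None
    day: int | None = None
    raw_text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day requires month")
        if self.month is not None and self.year is None:
            raise ValueError("month requires year")

    @property
    def is_empty(self) -> bool:
        return self.year is None

    @property
    def is_complete(self) -> bool:
        """True when year, month and day are all known."""
        return self.day is not None

    def to_date(self) -> datetime.date:
        """Convert a complete PartialDate to :class:`datetime.date`."""
        if not self.is_complete:
            raise ValueError(f"partial date {self.raw_text!r} is not complete")
        return datetime.date(self.year, self.month, self.day)

    def sort_key(self) -> tuple[int, int, int]:
        """Total order with unknown components sorting first."""
        return (self.year or 0, self.month or 0, self.day or 0)

    def __str__(self) -> str:
        if self.year is None:
            return ""
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}{self.month:02d}{self.day:02d}"


def parse_partial_date(text: str | None) -> PartialDate:
    """Parse a FAERS date field into a :class:`PartialDate`.

    Accepts 4-digit (``YYYY``), 6-digit (``YYYYMM``) and 8-digit
    (``YYYYMMDD``) strings.  Anything else — empty fields, non-digit text,
    out-of-range months or days — yields a fully absent date with the raw
    text retained.  This is a total function: it never raises.
    """
    raw = "" if text is None else str(text)
    s = raw.strip()
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return PartialDate(raw_text=raw)
    year = int(s[:4])
    if year == 0:
        return PartialDate(raw_text=raw)
    if len(s) == 4:
        return PartialDate(year=year, raw_text=raw)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        return PartialDate(raw_text=raw)
    if len(s) == 6:
        return PartialDate(year=year, month=month, raw_text=raw)
    day = int(s[6:8])
    if not 1 <= day <= calendar.monthrange(year, month)[1]:
        return PartialDate(raw_text=raw)
    return PartialDate(year=year, month=month, day=day, raw_text=raw)


def _check_table_kind(table_kind: str) -> str:
    kind = str(table_kind).upper()
    if kind not in TABLE_KINDS:
        raise ValueError(
            f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    return kind


def read_faers_table(path: str | Path, table_kind: str, *,
                     encoding: str = DEFAULT_ENCODING) -> list[dict[str, str | None]]:
    """Read one dollar-delimited FAERS table into a list of field-maps.

    Column names are upper-cased; field values are kept verbatim except that
    empty fields map to ``None``.  A line whose field count differs from the
    header raises :class:`FaersParseError` naming the 1-based line number —
    no line is ever silently dropped.

    Parameters
    ----------
    path : path to the ASCII file.
    table_kind : one of ``DEMO, DRUG, REAC, OUTC, THER, INDI`` (validation
        only; the column layout is taken from the file's own header).
    encoding : file encoding, Latin-1 by default as FAERS is distributed.
    """
    _check_table_kind(table_kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FAERS table not found: {path}")
    with open(path, "r", encoding=encoding, newline="") as fh:
        lines = fh.read().split("\n")
    # trailing newline produces one empty trailing chunk; drop it
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise FaersParseError("empty file (no header line)", path=path)
    header = [c.strip().upper() for c in lines[0].rstrip("\r").split(DELIMITER)]
    if MANDATORY_KEY not in header:
        raise FaersParseError(
            f"header is missing mandatory column {MANDATORY_KEY}", path=path)
    ncol = len(header)
    rows: list[dict[str, str | None]] = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\r").split(DELIMITER)
        if len(fields) != ncol:
            raise FaersParseError(
                f"expected {ncol} fields, found {len(fields)}",
                path=path, line_number=i)
        rows.append({col: (val if val != "" else None)
                     for col, val in zip(header, fields)})
    return rows


def write_faers_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                      table_kind: str, *, columns: Sequence[str] | None = None,
                      encoding: str = DEFAULT_ENCODING) -> Path:
    """Write field-maps as a dollar-delimited FAERS table.

    All rows must share a single key set (the column layout).  ``None``
    values are written as empty fields, so a write/read round trip is the
    identity on field values.  Values containing the ``$`` delimiter or a
    newline are rejected: the dialect has no escaping, so such a value could
    not survive a round trip.
    """
    _check_table_kind(table_kind)
    path = Path(path)
    rows = list(rows)
    if columns is None:
        if rows:
            columns = list(rows[0].keys())
        else:
            columns = [MANDATORY_KEY]
    columns = [str(c).upper() for c in columns]
    colset = set(columns)
    out_lines = [DELIMITER.join(columns)]
    for i, row in enumerate(rows):
        keys = {str(k).upper() for k in row.keys()}
        if keys != colset:
            raise ValueError(
                f"row {i} has keys {sorted(keys)} but table columns are "
                f"{sorted(colset)}: heterogeneous key sets cannot be written")
        upper = {str(k).upper(): v for k, v in row.items()}
        fields = []
        for col in columns:
            v = upper[col]
            s = "" if v is None else str(v)
            if DELIMITER in s or "\n" in s or "\r" in s:
                raise ValueError(
                    f"row {i}, column {col}: value {s!r} contains the "
                    "delimiter or a newline and cannot be round-tripped")
            fields.append(s)
        out_lines.append(DELIMITER.join(fields))
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding=encoding, newline="") as fh:
        fh.write("\n".join(out_lines) + "\n")
    return path


@dataclass
class RawTableBundle:
    """The six tables of one FAERS-style quarter, as parsed field-maps.

    ``orphan_counts`` reports, per non-DEMO table, how many rows carry a
    PRIMARYID that does not appear in the DEMO table; orphans are counted and
    surfaced, never silently dropped.
    """

    demo_rows: list[dict[str, str | None]] = field(default_factory=list)
    drug_rows: list[dict[str, str | None]] = field(default_factory=list)
    reac_rows: list[dict[str, str | None]] = field(default_factory=list)
    outc_rows: list[dict[str, str | None]] = field(default_factory=list)
    ther_rows: list[dict[str, str | None]] = field(default_factory=list)
    indi_rows: list[dict[str, str | None]] = field(default_factory=list)

    _ATTR_BY_KIND = {
        "DEMO": "demo_rows", "DRUG": "drug_rows", "REAC": "reac_rows",
        "OUTC": "outc_rows", "THER": "ther_rows", "INDI": "indi_rows",
    }

    def rows_for(self, table_kind: str) -> list[dict[str, str | None]]:
        return getattr(self, self._ATTR_BY_KIND[_check_table_kind(table_kind)])

    @property
    def orphan_counts(self) -> dict[str, int]:
        known = {r.get(MANDATORY_KEY) for r in self.demo_rows}
        counts: dict[str, int] = {}
        for kind in TABLE_KINDS[1:]:
            rows = self.rows_for(kind)
            counts[kind] = sum(1 for r in rows if r.get(MANDATORY_KEY) not in known)
        return counts


#: Conventional file names inside a quarter directory.
_BUNDLE_FILENAMES = {kind: f"{kind}.txt" for kind in TABLE_KINDS}


def read_bundle(directory: str | Path, *,
                encoding: str = DEFAULT_ENCODING) -> RawTableBundle:
    """Read a directory of six FAERS tables (``DEMO.txt`` … ``INDI.txt``).

    Missing non-DEMO files are treated as empty tables; a missing DEMO file
    is an error since every report must have a demographic row.
    """
    directory = Path(directory)
    bundle = RawTableBundle()
    for kind in TABLE_KINDS:
        path = directory / _BUNDLE_FILENAMES[kind]
        if not path.exists():
            if kind == "DEMO":
                raise FileNotFoundError(f"DEMO table not found in {directory}")
            continue
        bundle.rows_for(kind)[:] = read_faers_table(path, kind, encoding=encoding)
    return bundle


def write_bundle(bundle: RawTableBundle, directory: str | Path, *,
                 encoding: str = DEFAULT_ENCODING) -> Path:
    """Write all six tables of a bundle into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind in TABLE_KINDS:
        rows = bundle.rows_for(kind)
        write_faers_table(rows, directory / _BUNDLE_FILENAMES[kind], kind,
                          encoding=encoding)
    return directory
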