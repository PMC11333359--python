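"""Reading and writing FAERS-style quarterly ASCII tables.

The quarterly distribution is a set of dollar-sign-delimited text files
(DEMO/DRUG/REAC and friends) with a single header row.  Files are decoded
as Latin-1 with replacement since real-world quarters are not clean UTF-8.
Parsing is name-based: columns are looked up through an alias map, never by
position, so schema drift across years is handled in configuration.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "RPSR", "THER", "INDI")
ROLE_CODES = ("PS", "SS", "C", "I")

_QUARTER_RE = re.compile(r"^\d{4}Q[1-4]$")

#: age-unit code -> factor converting the stored value to years
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: occupation code -> reporter-type trichotomy
OCCUPATION_TO_REPORTER_TYPE: dict[str, str] = {
    "CN": "consumer",
    "MD": "health_professional",
    "PH": "health_professional",
    "OT": "health_professional",
    "HP": "health_professional",
    "RN": "health_professional",
}

MAX_AGE_YEARS = 130.0


def _check_quarter(quarter: str) -> str:
    if not _QUARTER_RE.match(quarter):
        raise ValueError(f"quarter label {quarter!r} does not match YYYYQ[1-4]")
    return quarter


@dataclass(frozen=True)
class RawTableRow:
    """One data line of a quarterly table, untyped and uncoerced."""

    table_kind: str
    quarter: str
    fields: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.table_kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.table_kind!r}")
        _check_quarter(self.quarter)

    def get(self, name: str, default: str = "") -> str:
        return self.fields.get(name, default)


@dataclass(frozen=True)
class ReportCase:
    """One safety report (the unit of counting after deduplication)."""

    primaryid: int
    caseid: int
    sex: str = "missing"  # female | male | missing
    age_years: float | None = None
    reporter_type: str = "other_missing"
    reporter_country: str | None = None
    quarter: str = "2014Q3"


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report, with its FAERS role code."""

    primaryid: int
    drugname: str
    prod_ai: str | None = None
    role_cod: str = "PS"

    def __post_init__(self) -> None:
        if self.role_cod not in ROLE_CODES:
            raise ValueError(f"role_cod {self.role_cod!r} not one of {ROLE_CODES}")


@dataclass(frozen=True)
class EventEntry:
    """One reaction preferred term on a report."""

    primaryid: int
    pt: str

    def __post_init__(self) -> None:
        if not self.pt.strip():
            raise ValueError("pt must be non-empty after trimming")


@dataclass
class DemoConventions:
    """Column names used to interpret a DEMO table.

    FAERS renamed several DEMO columns over the years (``gndr_cod`` vs
    ``sex``, ...); ``aliases`` maps canonical name -> list of accepted
    column headers, first match wins.
    """

    primaryid: str = "primaryid"
    caseid: str = "caseid"
    sex: str = "sex"
    age: str = "age"
    age_cod: str = "age_cod"
    occp_cod: str = "occp_cod"
    reporter_country: str = "reporter_country"
    aliases: dict[str, list[str]] = field(
        default_factory=lambda: {"sex": ["sex", "gndr_cod"]}
    )

    def lookup(self, row: RawTableRow, canonical: str) -> str:
        for name in self.aliases.get(canonical, [getattr(self, canonical)]):
            if name in row.fields:
                return row.fields[name]
        return row.fields.get(getattr(self, canonical), "")


def read_table(
    path: str | Path,
    table_kind: str,
    quarter: str,
    delimiter: str = "$",
    encoding: str = "latin-1",
) -> list[RawTableRow]:
    """Parse one quarterly ASCII file into raw rows.

    The first line is the header; every data line must carry the same
    number of fields.  Ragged lines are skipped with a warning (and the
    skip count logged once at the end) rather than aborting the load.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the header contains duplicate column names.
    """
    path = Path(path)
    if table_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    _check_quarter(quarter)
    with open(path, "r", encoding=encoding, errors="replace") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file, no header")
        header = header_line.rstrip("\r\n").split(delimiter)
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: duplicate column names in header")
        rows: list[RawTableRow] = []
        n_skipped = 0
        for lineno, line in enumerate(fh, start=2):
            values = line.rstrip("\r\n").split(delimiter)
            if len(values) != len(header):
                logger.warning(
                    "%s:%d: expected %d fields, got %d — line skipped",
                    path, lineno, len(header), len(values),
                )
                n_skipped += 1
                continue
            rows.append(
                RawTableRow(table_kind, quarter, dict(zip(header, values)))
            )
    if n_skipped:
        logger.warning("%s: skipped %d ragged line(s)", path, n_skipped)
    return rows


def _parse_int(value: str) -> int | None:
    try:
        return int(value.strip())
    except (ValueError, AttributeError):
        return None


def parse_demo(
    rows: Iterable[RawTableRow],
    conventions: DemoConventions | None = None,
) -> list[ReportCase]:
    """Type DEMO rows into :class:`ReportCase` records.

    Sex, reporter type and age are mapped through fixed codebooks;
    anything unmappable becomes missing.  Rows whose primaryid or caseid
    is not numeric are dropped with a warning — every retained value is a
    deterministic function of its input row.
    """
    conv = conventions or DemoConventions()
    cases: list[ReportCase] = []
    for row in rows:
        primaryid = _parse_int(conv.lookup(row, "primaryid"))
        caseid = _parse_int(conv.lookup(row, "caseid"))
        if primaryid is None or caseid is None:
            logger.warning("DEMO row with non-numeric id dropped: %r", dict(row.fields))
            continue
        sex_code = conv.lookup(row, "sex").strip().upper()
        sex = {"F": "female", "M": "male"}.get(sex_code, "missing")

        age_years: float | None = None
        age_raw = conv.lookup(row, "age").strip()
        unit = conv.lookup(row, "age_cod").strip().upper()
        if age_raw and unit in AGE_UNIT_TO_YEARS:
            try:
                age_years = float(age_raw) * AGE_UNIT_TO_YEARS[unit]
            except ValueError:
                age_years = None
            if age_years is not None and not (0.0 <= age_years <= MAX_AGE_YEARS):
                age_years = None

        occp = conv.lookup(row, "occp_cod").strip().upper()
        reporter_type = OCCUPATION_TO_REPORTER_TYPE.get(occp, "other_missing")
        country = conv.lookup(row, "reporter_country").strip() or None
        cases.append(
            ReportCase(
                primaryid=primaryid,
                caseid=caseid,
                sex=sex,
                age_years=age_years,
                reporter_type=reporter_type,
                reporter_country=country,
                quarter=row.quarter,
            )
        )
    return cases


def parse_drug(rows: Iterable[RawTableRow]) -> list[DrugEntry]:
    """Type DRUG rows; rows with a non-numeric primaryid or an unknown
    role code are dropped with a warning."""
    entries: list[DrugEntry] = []
    for row in rows:
        primaryid = _parse_int(row.get("primaryid"))
        role = row.get("role_cod").strip().upper()
        if primaryid is None or role not in ROLE_CODES:
            logger.warning("DRUG row dropped: %r", dict(row.fields))
            continue
        entries.append(
            DrugEntry(
                primaryid=primaryid,
                drugname=row.get("drugname"),
                prod_ai=row.get("prod_ai") or None,
                role_cod=role,
            )
        )
    return entries


def parse_reac(rows: Iterable[RawTableRow]) -> list[EventEntry]:
    """Type REAC rows; blank PTs and non-numeric ids are dropped."""
    entries: list[EventEntry] = []
    for row in rows:
        primaryid = _parse_int(row.get("primaryid"))
        pt = row.get("pt").strip()
        if primaryid is None or not pt:
            logger.warning("REAC row dropped: %r", dict(row.fields))
            continue
        entries.append(EventEntry(primaryid=primaryid, pt=pt))
    return entries


def _as_records(records: Sequence) -> tuple[list[str], list[list]]:
    first = records[0]
    if dataclasses.is_dataclass(first):
        cols = [f.name for f in dataclasses.fields(first)]
        return cols, [[getattr(r, c) for c in cols] for r in records]
    if isinstance(first, Mapping):
        cols = list(first.keys())
        return cols, [[r.get(c) for c in cols] for r in records]
    raise TypeError(f"cannot infer schema from record of type {type(first)}")


def write_delimited(
    records: pd.DataFrame | Sequence,
    path: str | Path,
    delimiter: str = "$",
    columns: Sequence[str] | None = None,
) -> Path:
    """Write tabular output as header + one line per record.

    Missing values (None/NaN) are rendered as empty fields.  Output is
    bit-stable for a fixed input and schema.  Accepts a DataFrame, a
    sequence of dataclasses, or a sequence of mappings; an empty sequence
    requires ``columns`` to emit the header.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        cols = list(columns) if columns is not None else list(records.columns)
        data = records[cols].itertuples(index=False, name=None)
    elif len(records) == 0:
        if columns is None:
            raise ValueError("empty record list requires explicit columns")
        cols, data = list(columns), []
    else:
        cols, data = _as_records(records)
        if columns is not None:
            idx = [cols.index(c) for c in columns]
            cols = list(columns)
            data = ([row[i] for i in idx] for row in data)

    def render(value) -> str:
        if value is None or (isinstance(value, float) and value != value):
            return ""
        return str(value)

    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for row in data:
            fh.write(delimiter.join(render(v) for v in row) + "\n")
    return path
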