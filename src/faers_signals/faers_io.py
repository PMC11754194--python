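"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS distributes each quarter as "$"-delimited ASCII files with a header
row: DEMO (demographics and case management), DRUG (one row per reported
drug with a role code), REAC (one row per MedDRA preferred term), THER
(therapy periods), OUTC (outcome codes) and DELE (caseids nullified by the
FDA).  This module maps those files onto typed records and back.

The dialect has no quoting; an embedded "$" inside a value would corrupt
the row, so on write it is replaced by a space (and logged).  All keys are
kept as strings — FAERS identifiers overflow 32-bit integers.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: FAERS outcome codes: death, life-threatening, hospitalisation, disability,
#: congenital anomaly, required intervention, other.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Drug role codes: primary suspect, secondary suspect, concomitant, interacting.
ROLE_CODES = ("PS", "SS", "C", "I")


@dataclass(slots=True)
class DemoRecord:
    """One demographic row; outcome codes are attached from OUTC."""

    primaryid: str
    caseid: str
    fda_dt: str = ""
    event_dt: str = ""
    sex: str = ""
    age: str = ""
    age_cod: str = ""
    occp_cod: str = ""
    reporter_country: str = ""
    outcomes: tuple[str, ...] = field(default=())


@dataclass(slots=True)
class DrugRecord:
    primaryid: str
    drug_seq: str = ""
    role_cod: str = ""
    drugname: str = ""
    prod_ai: str = ""


@dataclass(slots=True)
class ReacRecord:
    primaryid: str
    pt: str = ""


@dataclass(slots=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: str = ""
    start_dt: str = ""


@dataclass(slots=True)
class OutcRecord:
    primaryid: str
    outc_cod: str = ""


@dataclass(slots=True)
class DeleRecord:
    caseid: str = ""


#: table kind -> (record type, mandatory columns)
TABLE_SCHEMAS: dict[str, tuple[type, tuple[str, ...]]] = {
    "demo": (DemoRecord, ("primaryid", "caseid")),
    "drug": (DrugRecord, ("primaryid",)),
    "reac": (ReacRecord, ("primaryid",)),
    "ther": (TherRecord, ("primaryid",)),
    "outc": (OutcRecord, ("primaryid",)),
    "dele": (DeleRecord, ("caseid",)),
}


class TableFormatError(ValueError):
    """A mandatory column is absent from a table header."""


@dataclass(frozen=True, slots=True)
class ParsedDate:
    """Classification of a raw FAERS date string.

    ``kind`` is ``"exact"`` (valid 8-digit YYYYMMDD), ``"partial"`` (valid
    6-digit YYYYMM or 4-digit YYYY) or ``"missing"`` (empty or invalid).
    ``date`` is set only for exact dates; ``year``/``month`` where known.
    """

    kind: str
    date: datetime.date | None = None
    year: int | None = None
    month: int | None = None

    @property
    def is_exact(self) -> bool:
        return self.kind == "exact"


MISSING_DATE = ParsedDate("missing")


def parse_faers_date(raw: str | None) -> ParsedDate:
    """Classify a FAERS date string; total — never raises.

    FAERS dates are 8-digit YYYYMMDD when complete, 6-digit YYYYMM or
    4-digit YYYY when the reporter knew only part of the date.  Anything
    else — including calendar-invalid strings such as ``"20211332"`` — is
    treated as missing.
    """
    if raw is None:
        return MISSING_DATE
    s = str(raw).strip()
    if not s.isdigit():
        return MISSING_DATE
    if len(s) == 8:
        try:
            d = datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return MISSING_DATE
        return ParsedDate("exact", date=d, year=d.year, month=d.month)
    if len(s) == 6:
        year, month = int(s[:4]), int(s[4:6])
        if 1 <= month <= 12:
            return ParsedDate("partial", year=year, month=month)
        return MISSING_DATE
    if len(s) == 4:
        return ParsedDate("partial", year=int(s))
    return MISSING_DATE


def _field_names(record_type: type) -> list[str]:
    return [f.name for f in dc_fields(record_type) if f.name != "outcomes"]


def read_ascii_table(path: str | Path, table_kind: str) -> list:
    """Read one "$"-delimited table into typed records.

    Columns are mapped by header name (case-insensitive, order-independent);
    unknown columns are ignored and absent optional columns come back empty.
    Rows whose field count disagrees with the header are skipped and counted
    in a logged warning.  A missing mandatory column is a hard
    :class:`TableFormatError` naming the column.
    """
    record_type, mandatory = TABLE_SCHEMAS[table_kind]
    path = Path(path)
    wanted = _field_names(record_type)

    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TableFormatError(f"{path}: empty file, no header")
        header = [h.strip().lower() for h in header_line.rstrip("\r\n").split(DELIMITER)]
        for col in mandatory:
            if col not in header:
                raise TableFormatError(f"{path}: mandatory column {col!r} missing from header")
        ncol = len(header)
        positions = {name: header.index(name) for name in wanted if name in header}

        records = []
        malformed = 0
        for line in fh:
            parts = line.rstrip("\r\n").split(DELIMITER)
            if len(parts) != ncol:
                malformed += 1
                continue
            kwargs = {name: parts[idx].strip() for name, idx in positions.items()}
            records.append(record_type(**kwargs))

    if malformed:
        logger.warning("%s: skipped %d malformed line(s)", path, malformed)
    return records


def write_ascii_table(records: Sequence, path: str | Path, table_kind: str) -> Path:
    """Write homogeneous records as a "$"-delimited table; returns the path.

    Values containing the delimiter are sanitised (the "$" becomes a space)
    because the dialect has no quoting; occurrences are logged.
    """
    record_type, _ = TABLE_SCHEMAS[table_kind]
    path = Path(path)
    names = _field_names(record_type)
    sanitised = 0
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(names) + "\n")
        for rec in records:
            vals = []
            for name in names:
                v = str(getattr(rec, name))
                if DELIMITER in v:
                    v = v.replace(DELIMITER, " ")
                    sanitised += 1
                vals.append(v)
            fh.write(DELIMITER.join(vals) + "\n")
    if sanitised:
        logger.warning("%s: replaced embedded '$' with a space in %d value(s)", path, sanitised)
    return path


def attach_outcomes(demo_records: Iterable[DemoRecord], outc_records: Iterable[OutcRecord]) -> list[DemoRecord]:
    """Attach OUTC outcome codes to their DEMO records (returns demo list)."""
    by_id: dict[str, list[str]] = {}
    for o in outc_records:
        if o.outc_cod:
            by_id.setdefault(o.primaryid, []).append(o.outc_cod)
    demo = list(demo_records)
    for d in demo:
        codes = by_id.get(d.primaryid)
        if codes:
            d.outcomes = tuple(sorted(set(codes)))
    return demo


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert a homogeneous record list to a DataFrame (strings preserved)."""
    if not records:
        return pd.DataFrame()
    names = [f.name for f in dc_fields(type(records[0]))]
    return pd.DataFrame({n: [getattr(r, n) for r in records] for n in names})


def as_frame(obj, record_kind: str | None = None) -> pd.DataFrame:
    """Accept either a DataFrame or a record list; return a DataFrame."""
    if isinstance(obj, pd.DataFrame):
        return obj
    return records_to_frame(list(obj))
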