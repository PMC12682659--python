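"""Reading, writing and assembling FAERS-style quarterly ASCII tables.

FAERS publishes each quarter as five ``$``-delimited text tables: DEMO
(one row per report version, with demographics and the report keys),
DRUG (one row per drug entry, with a role code), REAC (one row per
MedDRA preferred term), THER (therapy start/end dates, linked to drug
entries by sequence number) and OUTC (outcome codes).  This module
parses those tables into plain row maps, then joins them on PRIMARYID
into :class:`Report` records that the rest of the pipeline consumes.

Parsing is deliberately strict and auditable: fields are split on a
literal ``$`` with no quoting dialect (FAERS publishes none), and any
line whose field count disagrees with the header is quarantined and
counted rather than silently dropped or repaired.
"""

from __future__ import annotations

import datetime
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: FAERS drug role codes: primary suspect, secondary suspect,
#: concomitant, interacting.
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

#: FAERS outcome codes: death, life-threatening, hospitalization,
#: disability, congenital anomaly, required intervention, other.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Minimum column sets per table; readers accept any superset (real
#: quarters added columns over the years).
REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "DEMO": (
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
        "sex", "wt", "wt_cod", "reporter_country", "occp_cod",
    ),
    "DRUG": ("primaryid", "drug_seq", "drugname", "role_cod"),
    "REAC": ("primaryid", "pt"),
    "THER": ("primaryid", "dsg_drug_seq", "start_dt"),
    "OUTC": ("primaryid", "outc_cod"),
}

_WS_RUN = re.compile(r"\s+")


class SchemaError(ValueError):
    """A table header is missing a required column."""


class AssemblyError(ValueError):
    """Report assembly received inputs it cannot join safely."""


def normalize_drug_name(name: str) -> str:
    """Normalize a verbatim drug name: uppercase, trim, collapse whitespace.

    No ingredient mapping or salt stripping is attempted; spelling
    harmonization beyond this belongs in user configuration.
    """
    return _WS_RUN.sub(" ", name.strip()).upper()


# ---------------------------------------------------------------------------
# Dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FaersDate:
    """A FAERS date field: a YYYYMMDD / YYYYMM / YYYY integer plus precision.

    FAERS stores dates as integers and permits partial precision.
    Partial dates are retained (for year-level summaries) but flagged so
    that day-resolution arithmetic can exclude them.

    Attributes
    ----------
    raw:
        The integer as stored, or ``None`` when the field was empty.
    precision:
        One of ``"day"``, ``"month"``, ``"year"``, ``"missing"``,
        ``"invalid"``.  ``"invalid"`` covers both non-numeric content
        and 8-digit values that are not real calendar dates.
    """

    raw: Optional[int]
    precision: str

    @classmethod
    def parse(cls, text: object) -> "FaersDate":
        s = str(text).strip() if text is not None else ""
        if not s:
            return cls(None, "missing")
        if not s.isdigit():
            return cls(None, "invalid")
        n = len(s)
        value = int(s)
        if n == 4:
            return cls(value, "year")
        if n == 6:
            month = value % 100
            if 1 <= month <= 12:
                return cls(value, "month")
            return cls(value, "invalid")
        if n == 8:
            try:
                datetime.date(value // 10000, (value // 100) % 100, value % 100)
            except ValueError:
                return cls(value, "invalid")
            return cls(value, "day")
        return cls(None, "invalid")

    @property
    def is_full(self) -> bool:
        """True when the date carries valid day-level precision."""
        return self.precision == "day"

    def as_date(self) -> Optional[datetime.date]:
        """The calendar date, or ``None`` unless day-precision."""
        if not self.is_full or self.raw is None:
            return None
        return datetime.date(self.raw // 10000, (self.raw // 100) % 100, self.raw % 100)

    @property
    def year(self) -> Optional[int]:
        if self.raw is None:
            return None
        if self.precision == "day":
            return self.raw // 10000
        if self.precision == "month":
            return self.raw // 100
        if self.precision == "year":
            return self.raw
        return None


MISSING_DATE = FaersDate(None, "missing")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportKey:
    """The (PRIMARYID, CASEID, FDA_DT) triple that drives deduplication.

    ``primaryid`` identifies one version of a report; ``caseid`` is
    shared across versions of the same case; ``fda_dt`` is the FDA
    receipt date as a YYYYMMDD integer (``None`` when missing).
    """

    primaryid: int
    caseid: int
    fda_dt: Optional[int] = None


@dataclass(frozen=True)
class DrugEntry:
    """One drug record within a report.

    ``role`` is the reporter-assigned causality role; only ``PS``
    (primary suspect) entries enter signal screening.
    """

    drugname: str
    role: str
    seq: Optional[int] = None
    therapy_start: FaersDate = MISSING_DATE
    therapy_end: FaersDate = MISSING_DATE

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(
                f"unknown drug role code {self.role!r}; expected one of {sorted(ROLE_CODES)}"
            )


@dataclass(frozen=True)
class Report:
    """One assembled safety report (a single DEMO row plus its children)."""

    key: ReportKey
    event_dt: FaersDate = MISSING_DATE
    age: Optional[float] = None
    age_cod: Optional[str] = None
    sex: Optional[str] = None
    wt: Optional[float] = None
    wt_cod: Optional[str] = None
    country: Optional[str] = None
    occupation: Optional[str] = None
    drugs: tuple[DrugEntry, ...] = ()
    reactions: tuple[str, ...] = ()
    outcomes: tuple[str, ...] = ()

    @property
    def primaryid(self) -> int:
        return self.key.primaryid

    def primary_suspect_names(self) -> tuple[str, ...]:
        """Distinct normalized PS drug names, in first-occurrence order."""
        seen: dict[str, None] = {}
        for d in self.drugs:
            if d.role == "PS" and d.drugname not in seen:
                seen[d.drugname] = None
        return tuple(seen)


# ---------------------------------------------------------------------------
# ASCII parsing
# ---------------------------------------------------------------------------

@dataclass
class ParsedTable:
    """Parse result for one ASCII table: rows plus a parse report."""

    table_kind: str
    columns: tuple[str, ...]
    rows: list[dict[str, str]]
    quarantined: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_quarantined(self) -> int:
        return len(self.quarantined)


def read_ascii_table(path: str | Path, table_kind: str) -> ParsedTable:
    """Read one ``$``-delimited FAERS table.

    The first line is the header.  Data lines whose field count differs
    from the header's are quarantined (recorded with their line number),
    never silently dropped.  Header names are lower-cased; any superset
    of the table's required columns is accepted.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SchemaError
        If the header lacks a required column for ``table_kind``.
    """
    kind = table_kind.upper()
    if kind not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        header_line = fh.readline().rstrip("\r\n")
        columns = tuple(c.strip().lower() for c in header_line.split(DELIMITER))
        missing = [c for c in REQUIRED_COLUMNS[kind] if c not in columns]
        if missing:
            raise SchemaError(
                f"{path.name}: {kind} header missing required column(s): {', '.join(missing)}"
            )
        table = ParsedTable(kind, columns, [])
        ncol = len(columns)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split(DELIMITER)
            if len(fields) != ncol:
                table.quarantined.append((lineno, line))
                continue
            table.rows.append(dict(zip(columns, fields)))
    if table.quarantined:
        logger.warning(
            "%s: quarantined %d malformed line(s)", path.name, table.n_quarantined
        )
    return table


def write_ascii_table(
    path: str | Path,
    columns: Sequence[str],
    rows: Iterable[Sequence[object]],
) -> None:
    """Write a ``$``-delimited table with one header line.

    ``None`` values are written as empty fields.  A value containing the
    delimiter would corrupt the file, so it is rejected.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(columns) + "\n")
        for row in rows:
            cells = []
            for v in row:
                s = "" if v is None else str(v)
                if DELIMITER in s:
                    raise ValueError(f"field value contains the {DELIMITER!r} delimiter: {s!r}")
                cells.append(s)
            fh.write(DELIMITER.join(cells) + "\n")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblyReport:
    """Bookkeeping from :func:`assemble_reports` for audit trails."""

    n_reports: int = 0
    orphans: dict[str, int] = field(default_factory=dict)
    invalid_roles: int = 0

    def total_orphans(self) -> int:
        return sum(self.orphans.values())


def _to_int(s: object) -> Optional[int]:
    try:
        return int(str(s).strip())
    except (TypeError, ValueError):
        return None


def _to_float(s: object) -> Optional[float]:
    try:
        return float(str(s).strip())
    except (TypeError, ValueError):
        return None


def _opt_str(s: object) -> Optional[str]:
    text = str(s).strip() if s is not None else ""
    return text or None


def assemble_reports(
    demo_rows: Sequence[Mapping[str, str]],
    drug_rows: Sequence[Mapping[str, str]] = (),
    reac_rows: Sequence[Mapping[str, str]] = (),
    ther_rows: Sequence[Mapping[str, str]] = (),
    outc_rows: Sequence[Mapping[str, str]] = (),
    *,
    tolerate_duplicate_primaryid: bool = False,
) -> tuple[list[Report], AssemblyReport]:
    """Join the five parsed tables into one :class:`Report` per DEMO row.

    DRUG/REAC/OUTC children attach by ``primaryid``; THER start/end
    dates attach to drug entries by ``(primaryid, dsg_drug_seq)``.
    Child rows with no matching DEMO row are orphans: counted per table
    and logged, never attached.  Drug entries keep file order
    (``drug_seq`` order as written).

    Duplicate ``primaryid`` within DEMO raises :class:`AssemblyError`
    unless ``tolerate_duplicate_primaryid`` is set (deduplication is
    meant to run on keys first).
    """
    rep = AssemblyReport()

    demo_ids: set[int] = set()
    for row in demo_rows:
        pid = _to_int(row.get("primaryid"))
        if pid is None:
            continue
        if pid in demo_ids and not tolerate_duplicate_primaryid:
            raise AssemblyError(
                f"duplicate primaryid {pid} in DEMO input; deduplicate keys first "
                "or pass tolerate_duplicate_primaryid=True"
            )
        demo_ids.add(pid)

    # (primaryid, dsg_drug_seq) -> (start, end)
    ther_by_key: dict[tuple[int, int], tuple[FaersDate, FaersDate]] = {}
    for row in ther_rows:
        pid = _to_int(row.get("primaryid"))
        seq = _to_int(row.get("dsg_drug_seq"))
        if pid is None or pid not in demo_ids:
            rep.orphans["THER"] = rep.orphans.get("THER", 0) + 1
            continue
        if seq is None:
            continue
        ther_by_key[(pid, seq)] = (
            FaersDate.parse(row.get("start_dt")),
            FaersDate.parse(row.get("end_dt")),
        )

    drugs_by_pid: dict[int, list[DrugEntry]] = {}
    for row in drug_rows:
        pid = _to_int(row.get("primaryid"))
        if pid is None or pid not in demo_ids:
            rep.orphans["DRUG"] = rep.orphans.get("DRUG", 0) + 1
            continue
        role = str(row.get("role_cod", "")).strip().upper()
        if role not in ROLE_CODES:
            rep.invalid_roles += 1
            continue
        seq = _to_int(row.get("drug_seq"))
        start, end = ther_by_key.get((pid, seq), (MISSING_DATE, MISSING_DATE)) \
            if seq is not None else (MISSING_DATE, MISSING_DATE)
        drugs_by_pid.setdefault(pid, []).append(
            DrugEntry(
                drugname=normalize_drug_name(str(row.get("drugname", ""))),
                role=role,
                seq=seq,
                therapy_start=start,
                therapy_end=end,
            )
        )

    reacs_by_pid: dict[int, list[str]] = {}
    for row in reac_rows:
        pid = _to_int(row.get("primaryid"))
        if pid is None or pid not in demo_ids:
            rep.orphans["REAC"] = rep.orphans.get("REAC", 0) + 1
            continue
        pt = str(row.get("pt", "")).strip()
        if pt:
            reacs_by_pid.setdefault(pid, []).append(pt)

    outc_by_pid: dict[int, list[str]] = {}
    for row in outc_rows:
        pid = _to_int(row.get("primaryid"))
        if pid is None or pid not in demo_ids:
            rep.orphans["OUTC"] = rep.orphans.get("OUTC", 0) + 1
            continue
        code = str(row.get("outc_cod", "")).strip().upper()
        if code in OUTCOME_CODES:
            outc_by_pid.setdefault(pid, []).append(code)

    reports: list[Report] = []
    seen: set[int] = set()
    for row in demo_rows:
        pid = _to_int(row.get("primaryid"))
        if pid is None or pid in seen:
            # tolerated duplicate versions: keep the first occurrence
            continue
        seen.add(pid)
        caseid = _to_int(row.get("caseid"))
        fda = FaersDate.parse(row.get("fda_dt"))
        reports.append(
            Report(
                key=ReportKey(
                    primaryid=pid,
                    caseid=caseid if caseid is not None else pid,
                    fda_dt=fda.raw if fda.precision != "invalid" else None,
                ),
                event_dt=FaersDate.parse(row.get("event_dt")),
                age=_to_float(row.get("age")),
                age_cod=_opt_str(row.get("age_cod")),
                sex=_opt_str(row.get("sex")),
                wt=_to_float(row.get("wt")),
                wt_cod=_opt_str(row.get("wt_cod")),
                country=_opt_str(row.get("reporter_country")),
                occupation=_opt_str(row.get("occp_cod")),
                drugs=tuple(drugs_by_pid.get(pid, ())),
                reactions=tuple(reacs_by_pid.get(pid, ())),
                outcomes=tuple(outc_by_pid.get(pid, ())),
            )
        )
    rep.n_reports = len(reports)
    if rep.total_orphans():
        logger.warning("assembly: %d orphan child row(s): %s", rep.total_orphans(), rep.orphans)
    return reports, rep


def read_quarter(directory: str | Path) -> tuple[list[Report], AssemblyReport]:
    """Read a quarter directory (DEMO/DRUG/REAC/THER/OUTC .txt) and assemble it."""
    directory = Path(directory)
    parsed = {
        kind: read_ascii_table(directory / f"{kind}.txt", kind)
        for kind in ("DEMO", "DRUG", "REAC", "THER", "OUTC")
    }
    return assemble_reports(
        parsed["DEMO"].rows,
        parsed["DRUG"].rows,
        parsed["REAC"].rows,
        parsed["THER"].rows,
        parsed["OUTC"].rows,
    )


def export_reports(reports: Sequence[Report], path: str | Path) -> None:
    """Write a flat, delimited audit export of assembled reports.

    One line per report; drugs, reactions and outcomes are packed into
    ``;``-separated lists.  Intended for eyeballing and diffing, not for
    re-ingestion.
    """
    cols = (
        "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex",
        "wt", "wt_cod", "country", "occupation", "drugs", "reactions", "outcomes",
    )
    rows = []
    for r in reports:
        rows.append((
            r.key.primaryid, r.key.caseid, r.key.fda_dt, r.event_dt.raw,
            r.age, r.age_cod, r.sex, r.wt, r.wt_cod, r.country, r.occupation,
            ";".join(f"{d.drugname}[{d.role}]" for d in r.drugs),
            ";".join(r.reactions),
            ";".join(r.outcomes),
        ))
    write_ascii_table(path, cols, rows)
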