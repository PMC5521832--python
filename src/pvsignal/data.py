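"""Relational data model for a four-table spontaneous-reporting extract.

The schema mirrors the public structure of large spontaneous-reporting
systems such as JADER: one demographics row per report (``demo``), and
child tables of drug records (``drug``), adverse-event records coded as
MedDRA preferred terms (``reac``), and primary-disease / history terms
(``hist``), all keyed by a case identifier. Reports — not drug-event
pairs — are the counting unit for every downstream statistic.

Case definition is by standardized MedDRA query (SMQ): a report is an
event case iff at least one of its preferred-term codes falls in the
union of the configured SMQ term sets.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from ._util import SchemaError
from .partialdate import PartialDate

logger = logging.getLogger(__name__)

ROLE_SUSPECTED = "suspected"
ROLE_CONCOMITANT = "concomitant"
ROLE_INTERACTING = "interacting"
ROLE_CODES = frozenset({ROLE_SUSPECTED, ROLE_CONCOMITANT, ROLE_INTERACTING})

#: Closed vocabulary of decade age bands; anything else maps to "unknown".
AGE_CATEGORIES = tuple(f"{10 * i}-{10 * i + 9}" for i in range(10)) + ("unknown",)

REQUIRED_COLUMNS = {
    "demo": ("case_id", "sex", "age_category", "report_year"),
    "drug": ("case_id", "drug_name", "role_code", "start_date", "end_date"),
    "reac": ("case_id", "pt_code", "pt_name", "onset_date", "outcome"),
    "hist": ("case_id", "term"),
}


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: str
    age_category: str
    report_year: Optional[int]

    def __post_init__(self) -> None:
        if not self.case_id:
            raise SchemaError("case_id must be non-empty")


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    role_code: str
    start_date: Optional[PartialDate] = None
    end_date: Optional[PartialDate] = None

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise SchemaError(
                f"role_code {self.role_code!r} not in {sorted(ROLE_CODES)}"
            )


@dataclass(frozen=True)
class EventRecord:
    case_id: str
    pt_code: str
    pt_name: str = ""
    onset_date: Optional[PartialDate] = None
    outcome: str = ""

    def __post_init__(self) -> None:
        if not (self.pt_code.isdigit() and len(self.pt_code) == 8):
            raise SchemaError(f"pt_code must be an 8-digit string: {self.pt_code!r}")


@dataclass(frozen=True)
class HistoryRecord:
    case_id: str
    term: str

    def __post_init__(self) -> None:
        if not self.term:
            raise SchemaError("history term must be non-empty")


@dataclass(frozen=True)
class SMQTermSet:
    """A standardized MedDRA query: a named, flat set of preferred terms."""

    smq_code: int
    label: str
    pt_codes: frozenset

    def __post_init__(self) -> None:
        if not self.pt_codes:
            raise SchemaError(f"SMQ {self.smq_code} has no preferred terms")


@dataclass
class CaseReport:
    """One spontaneous report: demographics plus all child records."""

    case_id: str
    demo: Optional[DemoRecord]
    drugs: List[DrugRecord] = field(default_factory=list)
    events: List[EventRecord] = field(default_factory=list)
    history: List[HistoryRecord] = field(default_factory=list)
    is_te: Optional[bool] = None  # set by flag_event_cases

    @property
    def is_stub(self) -> bool:
        """True when child rows referenced a case id absent from demo."""
        return self.demo is None

    @property
    def age_category(self) -> str:
        return self.demo.age_category if self.demo else "unknown"

    @property
    def primary_disease(self) -> Optional[str]:
        """First history term, by file order (the reported primary disease)."""
        return self.history[0].term if self.history else None


@dataclass
class LoadReport:
    """Audit counts from table loading; totals always reconcile."""

    n_reports: int = 0
    n_stub_reports: int = 0
    duplicate_demo_rows: int = 0
    orphan_rows: Dict[str, int] = field(default_factory=dict)
    row_counts: Dict[str, int] = field(default_factory=dict)


def normalize_drug_name(name: str, name_map: Optional[Mapping[str, str]] = None) -> str:
    """Trim, case-fold, then apply an optional alias map.

    The alias map collapses brand or component spellings onto one
    non-proprietary combination name (e.g. "drospirenone/ethinyl
    estradiol" -> "Drospirenone-EE"). Keys are compared case-folded.
    """
    key = " ".join(name.strip().split()).casefold()
    if name_map:
        folded = {k.casefold(): v for k, v in name_map.items()}
        return folded.get(key, key)
    return key


def _check_columns(df: pd.DataFrame, table: str) -> None:
    for col in REQUIRED_COLUMNS[table]:
        if col not in df.columns:
            raise SchemaError(f"table {table!r} is missing column {col!r}")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def read_tables(
    demo_path,
    drug_path,
    reac_path,
    hist_path,
    name_map: Optional[Mapping[str, str]] = None,
) -> Tuple[Dict[str, CaseReport], LoadReport]:
    """Read and join the four tables into one :class:`CaseReport` per case.

    Returns ``(reports, load_report)`` where ``reports`` maps case id to
    report in demo-file order (stubs appended after). Duplicate demo rows
    keep the first occurrence; child rows whose case id is absent from demo
    are attached to stub reports and counted rather than dropped, so totals
    remain auditable.
    """
    frames = {
        "demo": _read_csv(demo_path),
        "drug": _read_csv(drug_path),
        "reac": _read_csv(reac_path),
        "hist": _read_csv(hist_path),
    }
    for table, df in frames.items():
        _check_columns(df, table)

    report = LoadReport(row_counts={t: len(df) for t, df in frames.items()})
    reports: Dict[str, CaseReport] = {}

    for row in frames["demo"].itertuples(index=False):
        cid = str(row.case_id)
        if cid in reports:
            report.duplicate_demo_rows += 1
            logger.warning("duplicate demo row for case %s; keeping first", cid)
            continue
        year = str(row.report_year).strip()
        age = str(row.age_category).strip()
        reports[cid] = CaseReport(
            case_id=cid,
            demo=DemoRecord(
                case_id=cid,
                sex=str(row.sex).strip(),
                age_category=age if age in AGE_CATEGORIES else "unknown",
                report_year=int(year) if year.isdigit() else None,
            ),
        )

    def attach(table: str, make_record) -> None:
        orphans = 0
        for row in frames[table].itertuples(index=False):
            cid = str(row.case_id)
            if cid not in reports:
                orphans += 1
                reports[cid] = CaseReport(case_id=cid, demo=None)
            rec = make_record(cid, row)
            getattr(reports[cid], {"drug": "drugs", "reac": "events", "hist": "history"}[table]).append(rec)
        report.orphan_rows[table] = orphans

    attach(
        "drug",
        lambda cid, r: DrugRecord(
            case_id=cid,
            drug_name=normalize_drug_name(str(r.drug_name), name_map),
            role_code=str(r.role_code).strip().casefold(),
            start_date=PartialDate.parse_optional(r.start_date),
            end_date=PartialDate.parse_optional(r.end_date),
        ),
    )
    attach(
        "reac",
        lambda cid, r: EventRecord(
            case_id=cid,
            pt_code=str(r.pt_code).strip(),
            pt_name=str(r.pt_name).strip(),
            onset_date=PartialDate.parse_optional(r.onset_date),
            outcome=str(r.outcome).strip(),
        ),
    )
    attach("hist", lambda cid, r: HistoryRecord(case_id=cid, term=str(r.term).strip()))

    report.n_reports = len(reports)
    report.n_stub_reports = sum(1 for r in reports.values() if r.is_stub)
    return reports, report


def write_tables(reports: Iterable[CaseReport], outdir) -> Dict[str, Path]:
    """Write reports back out as the four CSV tables (round-trip support)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, hist = [], [], [], []
    for r in reports:
        if r.demo is not None:
            demo.append(
                {
                    "case_id": r.case_id,
                    "sex": r.demo.sex,
                    "age_category": r.demo.age_category,
                    "report_year": "" if r.demo.report_year is None else r.demo.report_year,
                }
            )
        for d in r.drugs:
            drug.append(
                {
                    "case_id": r.case_id,
                    "drug_name": d.drug_name,
                    "role_code": d.role_code,
                    "start_date": d.start_date.isoformat() if d.start_date else "",
                    "end_date": d.end_date.isoformat() if d.end_date else "",
                }
            )
        for e in r.events:
            reac.append(
                {
                    "case_id": r.case_id,
                    "pt_code": e.pt_code,
                    "pt_name": e.pt_name,
                    "onset_date": e.onset_date.isoformat() if e.onset_date else "",
                    "outcome": e.outcome,
                }
            )
        for h in r.history:
            hist.append({"case_id": r.case_id, "term": h.term})
    paths = {}
    for name, rows in [("demo", demo), ("drug", drug), ("reac", reac), ("hist", hist)]:
        path = outdir / f"{name}.csv"
        pd.DataFrame(rows, columns=REQUIRED_COLUMNS[name]).to_csv(path, index=False)
        paths[name] = path
    return paths


def load_smq_terms(path=None) -> List[SMQTermSet]:
    """Load SMQ term sets from a ``smq_code,pt_code,pt_name`` CSV.

    With no path, loads the packaged thromboembolism SMQ triple
    (arterial 20000082; vessel type unspecified / mixed 20000083;
    venous 20000084).
    """
    if path is None:
        ref = resources.files("pvsignal.datasets") / "smq_thromboembolism.csv"
        with resources.as_file(ref) as p:
            df = _read_csv(p)
    else:
        df = _read_csv(path)
    for col in ("smq_code", "pt_code"):
        if col not in df.columns:
            raise SchemaError(f"SMQ file is missing column {col!r}")
    out = []
    for code, grp in df.groupby("smq_code", sort=True):
        label = str(grp["pt_name"].iloc[0]) if "pt_name" in grp else ""
        out.append(
            SMQTermSet(
                smq_code=int(code),
                label=label,
                pt_codes=frozenset(grp["pt_code"].astype(str)),
            )
        )
    return out


def smq_pt_union(smqs: Sequence[SMQTermSet]) -> frozenset:
    u: Set[str] = set()
    for s in smqs:
        u |= s.pt_codes
    return frozenset(u)


def filter_suspected(report: CaseReport) -> List[DrugRecord]:
    """Drug records with the 'suspected' role code, order preserved."""
    return [d for d in report.drugs if d.role_code == ROLE_SUSPECTED]


def flag_te(report: CaseReport, smqs: Sequence[SMQTermSet]) -> bool:
    """True iff any event preferred term falls in the SMQ union.

    A report with several matching terms is still one case.
    """
    if not smqs:
        raise ValueError("at least one SMQ term set is required")
    union = smq_pt_union(smqs)
    return any(e.pt_code in union for e in report.events)


def flag_event_cases(
    reports: Mapping[str, CaseReport], smqs: Sequence[SMQTermSet]
) -> int:
    """Set ``is_te`` on every report in place; returns the case count."""
    union = smq_pt_union(smqs)
    n = 0
    for r in reports.values():
        r.is_te = any(e.pt_code in union for e in r.events)
        n += r.is_te
    return n


def exposure_index(
    reports: Mapping[str, CaseReport]
) -> Tuple[Dict[str, Set[str]], Set[str]]:
    """Suspected-exposure case-id sets per drug, plus the event case-id set.

    A case id appears at most once per drug, however many suspected
    records name that drug.
    """
    by_drug: Dict[str, Set[str]] = {}
    te_cases: Set[str] = set()
    for r in reports.values():
        for d in filter_suspected(r):
            by_drug.setdefault(d.drug_name, set()).add(r.case_id)
        if r.is_te:
            te_cases.add(r.case_id)
    return by_drug, te_cases


def to_dict(obj) -> dict:  # pragma: no cover - convenience
    return dataclasses.asdict(obj)
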