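"""Disproportionality signal detection on 2x2 report contingency tables.

For a target drug and an adverse-event class, reports are cross-classified

===============  ===========  ==================
                 event (TE)   all other events
===============  ===========  ==================
target drug      a            b
all other drugs  c            d
===============  ===========  ==================

and two disproportionality measures are computed:

* reporting odds ratio  ROR = ad / bc, with a Wald 95% CI on the log scale,
  exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d));
* proportional reporting ratio  PRR = [a/(a+b)] / [c/(c+d)].

The PRR confidence interval deliberately reuses the ROR-style standard
error sqrt(1/a + 1/b + 1/c + 1/d). This is a reproduction-driven choice:
published signal tables for the combined estrogen-progestin / thrombo-
embolism analysis this package replays are reproduced only under that SE,
not under the textbook PRR SE sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).

The chi-square statistic carries the Yates continuity correction
(again what the replayed tables require):

    chi2 = n (|ad - bc| - n/2)^2 / [(a+b)(c+d)(a+c)(b+d)],

clamped to zero when |ad - bc| <= n/2.

Signal criteria follow common regulatory practice: the ROR signal needs at
least 2 cases and a lower CI bound above 1; the PRR signal needs at least
3 cases, PRR >= 2 and chi-square >= 4. Tables with a zero cell are
suppressed (dash in the report) rather than continuity-corrected.

Age-stratified estimates compare each stratum's exposed reports against
the ENTIRE remaining database, not the stratum: c and d are computed from
the full event and grand totals. The replayed published stratified rows
match only under this convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import UserInputError, round_half_up
from .data import AGE_CATEGORIES, CaseReport, exposure_index

Z975 = 1.959963984540054  # standard normal 97.5% quantile


class Suppression(str, Enum):
    NONE = "none"
    LT2_CASES = "lt2_cases"  # ROR suppressed: fewer than 2 cases
    LT3_CASES = "lt3_cases"  # PRR / chi2 suppressed: fewer than 3 cases
    NO_NONCASE = "no_noncase"  # b = 0: everything suppressed


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts a, b, c, d of the drug x event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise UserInputError(f"negative cell in {self!r}")
        if self.n == 0:
            raise UserInputError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_margins(
        cls, case: int, total: int, event_total: int, n_total: int
    ) -> "ContingencyTable":
        """Rebuild the 2x2 table from report-level margins.

        ``case`` = reports with the drug and the event, ``total`` = reports
        with the drug, ``event_total`` = all event reports in the database,
        ``n_total`` = database size. This is how published count columns
        ("Case", "Total") are replayed into full tables.
        """
        a = case
        b = total - case
        c = event_total - case
        d = n_total - event_total - b
        if min(a, b, c, d) < 0:
            raise UserInputError(
                f"margins (case={case}, total={total}, event_total={event_total}, "
                f"n_total={n_total}) produce a negative cell"
            )
        return cls(a, b, c, d)

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


def compute_ror(t: ContingencyTable) -> Optional[Tuple[float, float, float]]:
    """ROR point estimate and 95% Wald CI, or None if any cell is zero."""
    if t.has_zero_cell():
        return None
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return ror, ror * math.exp(-Z975 * se), ror * math.exp(Z975 * se)


def compute_prr(t: ContingencyTable) -> Optional[Tuple[float, float, float]]:
    """PRR point estimate and 95% CI (ROR-style SE; see module docstring)."""
    if t.has_zero_cell():
        return None
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return prr, prr * math.exp(-Z975 * se), prr * math.exp(Z975 * se)


def yates_chi2(t: ContingencyTable) -> Optional[float]:
    """Yates-corrected chi-square, clamped to 0; None on a zero margin."""
    if 0 in (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d):
        return None
    n = t.n
    delta = abs(t.a * t.d - t.b * t.c) - n / 2
    if delta <= 0:
        return 0.0
    return n * delta * delta / ((t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d))


@dataclass
class SignalResult:
    """Disproportionality estimates and signal flags for one drug/stratum."""

    drug: str
    stratum: str
    table: ContingencyTable
    ror: Optional[float] = None
    ror_ci: Optional[Tuple[float, float]] = None
    prr: Optional[float] = None
    prr_ci: Optional[Tuple[float, float]] = None
    chi2: Optional[float] = None
    ror_signal: bool = False
    prr_signal: bool = False
    suppressed: Suppression = Suppression.NONE

    @property
    def case_count(self) -> int:
        return self.table.a

    @property
    def total(self) -> int:
        return self.table.a + self.table.b

    @property
    def reporting_ratio(self) -> Optional[float]:
        """Percent of the drug's reports that are event cases, 100 a/(a+b)."""
        return 100.0 * self.table.a / self.total if self.total else None


def evaluate_table(drug: str, t: ContingencyTable, stratum: str = "all") -> SignalResult:
    """Compute all statistics, suppression markers, and signal flags.

    Suppression mirrors report-table dash conventions: no non-case
    reports (b = 0) suppresses everything; < 2 cases suppresses the ROR;
    < 3 cases suppresses PRR and chi-square; any other zero cell
    suppresses the affected statistics (no Haldane correction).
    """
    r = SignalResult(drug=drug, stratum=stratum, table=t)
    if t.b == 0 and t.a > 0:
        r.suppressed = Suppression.NO_NONCASE
        return r
    if t.a < 2:
        r.suppressed = Suppression.LT2_CASES
    elif t.a < 3:
        r.suppressed = Suppression.LT3_CASES

    if r.suppressed is not Suppression.LT2_CASES:
        ror = compute_ror(t)
        if ror is not None:
            r.ror, r.ror_ci = ror[0], (ror[1], ror[2])
    if r.suppressed is Suppression.NONE:
        prr = compute_prr(t)
        if prr is not None:
            r.prr, r.prr_ci = prr[0], (prr[1], prr[2])
        r.chi2 = yates_chi2(t)

    r.ror_signal = bool(t.a >= 2 and r.ror_ci is not None and r.ror_ci[0] > 1)
    r.prr_signal = bool(
        t.a >= 3
        and r.prr is not None
        and r.chi2 is not None
        and r.prr >= 2
        and r.chi2 >= 4
    )
    return r


def stratified_analysis(
    reports: Mapping[str, CaseReport],
    drug_case_ids: frozenset,
    te_case_ids: frozenset,
    strata: Sequence[str] = AGE_CATEGORIES[1:6],
    drug: str = "drug",
) -> List[SignalResult]:
    """Per-age-band signal estimates with the full-database comparator.

    For stratum s: a = event cases in s exposed to the drug, b = exposed
    non-cases in s, while c and d come from the event total and grand
    total of the WHOLE database. Reports with unknown age fall in an
    "unknown" stratum and are excluded from the named bands.
    """
    n_total = len(reports)
    te_total = len(te_case_ids)
    out = []
    for s in strata:
        in_stratum = {
            cid for cid in drug_case_ids if reports[cid].age_category == s
        }
        a = len(in_stratum & te_case_ids)
        b = len(in_stratum) - a
        t = ContingencyTable(a, b, te_total - a, n_total - te_total - b)
        out.append(evaluate_table(drug, t, stratum=s))
    return out


def two_way_frequency(
    reports: Mapping[str, CaseReport],
    x: str = "age_category",
    y: str = "primary_disease",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way counts of report attributes and column-conditional proportions.

    The proportions table (one column per X level, summing to 1) is the
    numeric content of a mosaic plot of Y by X. All-zero columns are kept
    with zero proportions so empty categories stay visible.
    """
    rows = []
    for r in reports.values():
        rows.append({"x": getattr(r, x), "y": getattr(r, y)})
    df = pd.DataFrame(rows).dropna()
    if df.empty:
        empty = pd.DataFrame()
        return empty, empty
    counts = pd.crosstab(df["y"], df["x"])
    colsums = counts.sum(axis=0)
    props = counts.div(colsums.where(colsums > 0, other=np.nan), axis=1).fillna(0.0)
    return counts, props


class DisproportionalityModel:
    """Disproportionality screen for one or more drugs against an event class.

    Follows the model/results idiom: construct from data, call
    :meth:`fit`, inspect the returned :class:`DisproportionalityResults`.

    Parameters
    ----------
    tables
        Mapping of drug label to :class:`ContingencyTable`.
    strata_tables
        Optional mapping of (drug, stratum) to tables for age-stratified
        rows.
    """

    def __init__(
        self,
        tables: Mapping[str, ContingencyTable],
        strata_tables: Optional[Mapping[Tuple[str, str], ContingencyTable]] = None,
    ) -> None:
        if not tables:
            raise UserInputError("no contingency tables supplied")
        self.tables = dict(tables)
        self.strata_tables = dict(strata_tables or {})

    @classmethod
    def from_reports(
        cls,
        reports: Mapping[str, CaseReport],
        drugs: Sequence[str],
        strata: Sequence[str] = AGE_CATEGORIES[1:6],
        combined_label: Optional[str] = None,
    ) -> "DisproportionalityModel":
        """Build tables from flagged case reports for each drug (and their
        union if ``combined_label`` is given), plus age-stratified tables."""
        from .data import normalize_drug_name

        by_drug, te_cases = exposure_index(reports)
        te_cases = frozenset(te_cases)
        n_total = len(reports)
        te_total = len(te_cases)

        # lookup under the same normalization the loader applied,
        # but label results with the display name as given
        def cases_of(d: str) -> frozenset:
            return frozenset(by_drug.get(normalize_drug_name(d), set()))

        groups: Dict[str, frozenset] = {}
        if combined_label is not None:
            groups[combined_label] = frozenset().union(*(cases_of(d) for d in drugs))
        for d in drugs:
            groups[d] = cases_of(d)

        tables, strata_tables = {}, {}
        for label, cids in groups.items():
            a = len(cids & te_cases)
            b = len(cids) - a
            tables[label] = ContingencyTable(a, b, te_total - a, n_total - te_total - b)
            for res in stratified_analysis(reports, cids, te_cases, strata, drug=label):
                strata_tables[(label, res.stratum)] = res.table
        return cls(tables, strata_tables)

    def fit(self) -> "DisproportionalityResults":
        results = [evaluate_table(d, t) for d, t in self.tables.items()]
        for (d, s), t in self.strata_tables.items():
            results.append(evaluate_table(d, t, stratum=s))
        return DisproportionalityResults(self, results)


@dataclass
class DisproportionalityResults:
    """Fitted signal screen; rows in drug-then-stratum order."""

    model: DisproportionalityModel
    results: List[SignalResult] = field(default_factory=list)

    def __iter__(self):
        return iter(self.results)

    def by_drug(self, drug: str, stratum: str = "all") -> SignalResult:
        for r in self.results:
            if r.drug == drug and r.stratum == stratum:
                return r
        raise KeyError((drug, stratum))

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """One row per drug/stratum. With ``rounded`` (report style) the
        estimates are half-up rounded to 1 decimal and suppressed cells
        carry their marker code instead of a number."""
        rows = []
        for r in self.results:
            fmt = (lambda v: round_half_up(v, 1)) if rounded else (lambda v: v)
            sup = r.suppressed.value

            def cell(value, sup=sup):
                if value is None:
                    # suppressed cells carry their marker; a zero cell with
                    # no marker (pathological toy tables) stays blank
                    return sup if (rounded and sup != "none") else None
                return fmt(value)

            rows.append(
                {
                    "drug": r.drug,
                    "stratum": r.stratum,
                    "case": r.case_count,
                    "total": r.total,
                    "non_case": r.table.b,
                    "reporting_ratio": fmt(r.reporting_ratio)
                    if r.reporting_ratio is not None
                    else None,
                    "prr": cell(r.prr, sup),
                    "prr_lo": cell(r.prr_ci[0] if r.prr_ci else None, sup),
                    "prr_hi": cell(r.prr_ci[1] if r.prr_ci else None, sup),
                    "chi2": cell(r.chi2, sup),
                    "ror": cell(r.ror, sup),
                    "ror_lo": cell(r.ror_ci[0] if r.ror_ci else None, sup),
                    "ror_hi": cell(r.ror_ci[1] if r.ror_ci else None, sup),
                    "ror_signal": r.ror_signal,
                    "prr_signal": r.prr_signal,
                    "suppressed": sup,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame(rounded=True)
        lines = ["Disproportionality screen", "=" * 72]
        lines.append(df.to_string(index=False))
        return "\n".join(lines)
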