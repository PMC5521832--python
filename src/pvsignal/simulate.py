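"""Seeded generator of four-table spontaneous-reporting datasets.

The generator emulates the structure of a JADER-style extract — one demo
row per report and child drug/reac/hist tables with role codes, partial
dates, and MedDRA-coded events — with known ground truth so the whole
analysis chain closes the loop:

* per-drug event effect sizes via an odds-multiplier model: a report's
  odds of being an event case are ``background odds x multiplier`` for
  each exposed drug, so the realized reporting odds ratio of a drug
  targets its configured multiplier;
* Weibull time-to-onset laws: event cases exposed to a study drug get
  ``onset = start + round(Weibull(scale, shape))`` days;
* planted association rules: :func:`plant_transactions` lays out
  transactions whose co-occurrence counts equal the planted counts
  exactly.

The emitted CSVs are the exact dialect consumed by
:func:`pvsignal.data.read_tables`; ``manifest.json`` records configured
parameters and realized counts. A fixed seed gives byte-identical files.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._util import UserInputError
from .data import load_smq_terms, smq_pt_union
from .disproportionality import ContingencyTable
from .mining import TE_ITEM, Transaction

#: replay_contingency: rebuild a 2x2 table from report-level margins.
replay_contingency = ContingencyTable.from_margins

_BACKGROUND_DRUGS = [
    "acetaminophen",
    "amlodipine besylate",
    "loxoprofen",
    "lansoprazole",
    "carbamazepine",
    "methotrexate",
    "atorvastatin",
    "prednisolone",
]
_BACKGROUND_PTS = [
    ("99000001", "Nausea"),
    ("99000002", "Rash"),
    ("99000003", "Hepatic function abnormal"),
    ("99000004", "Headache"),
    ("99000005", "Interstitial lung disease"),
    ("99000006", "Pyrexia"),
]
_AGE_BANDS = ("10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79")
#: background age mix of the simulated database (reporting-system shaped:
#: most reports from older patients, study-drug users skewed younger)
_AGE_WEIGHTS = (0.02, 0.06, 0.10, 0.14, 0.18, 0.26, 0.24)


@dataclass(frozen=True)
class DrugSpec:
    """Ground-truth behaviour of one study drug in the simulation."""

    name: str
    exposure_prevalence: float = 0.003
    te_odds_multiplier: float = 1.0
    tto_scale_alpha: float = 200.0  # days
    tto_shape_beta: float = 0.9
    age_distribution: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.exposure_prevalence <= 1:
            raise UserInputError("exposure_prevalence must be in [0, 1]")
        if self.te_odds_multiplier <= 0:
            raise UserInputError("te_odds_multiplier must be positive")
        if self.tto_scale_alpha <= 0 or self.tto_shape_beta <= 0:
            raise UserInputError("Weibull parameters must be positive")


@dataclass(frozen=True)
class PlantedRule:
    """A ground-truth association rule: ``n_antecedent`` transactions carry
    the antecedent itemset, ``n_with_te`` of them also carry the event item."""

    antecedent_items: Tuple[str, ...]
    n_antecedent: int
    n_with_te: int

    def __post_init__(self) -> None:
        if not self.antecedent_items:
            raise UserInputError("a planted rule needs at least one item")
        if not 0 <= self.n_with_te <= self.n_antecedent:
            raise UserInputError("need 0 <= n_with_te <= n_antecedent")


@dataclass
class SimConfig:
    n_reports: int = 50_000
    background_te_rate: float = 0.043  # event reports / all reports (~4.3%)
    drugs: List[DrugSpec] = field(default_factory=list)
    history_terms: List[Tuple[str, float]] = field(
        default_factory=lambda: [
            ("dysmenorrhea", 0.01),
            ("endometriosis", 0.006),
            ("contraception", 0.004),
            ("uterine leiomyoma", 0.005),
            ("hypertension", 0.08),
            ("smoking", 0.03),
            ("anemia", 0.02),
        ]
    )
    rules: List[PlantedRule] = field(default_factory=list)
    seed: int = 0
    study_start: datetime.date = datetime.date(2004, 4, 1)
    study_end: datetime.date = datetime.date(2014, 11, 30)
    partial_month_fraction: float = 0.07
    partial_year_fraction: float = 0.03
    sex_female_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise UserInputError("n_reports must be >= 1")
        for p in (
            self.background_te_rate,
            self.partial_month_fraction,
            self.partial_year_fraction,
            self.sex_female_fraction,
        ):
            if not 0 <= p <= 1:
                raise UserInputError("probabilities must lie in [0, 1]")


def _dates_to_iso(
    days: np.ndarray, origin: datetime.date, rng: np.random.Generator,
    p_month: float, p_year: float,
) -> List[str]:
    """Day offsets -> ISO strings, a random fraction truncated to
    month/year precision to exercise partial-date handling."""
    u = rng.random(days.size)
    out = []
    for off, ui in zip(days.tolist(), u.tolist()):
        d = origin + datetime.timedelta(days=int(off))
        if ui < p_year:
            out.append(f"{d.year:04d}")
        elif ui < p_year + p_month:
            out.append(f"{d.year:04d}-{d.month:02d}")
        else:
            out.append(d.isoformat())
    return out


def simulate_tables(
    config: SimConfig,
) -> Tuple[Dict[str, pd.DataFrame], Dict]:
    """Draw a full four-table dataset in memory; returns (tables, manifest).

    Exposure indicators are drawn independently per drug; the event flag
    is Bernoulli with odds ``background odds x product of multipliers of
    exposed drugs``, making each drug's population reporting odds ratio
    equal its configured multiplier (for independent exposures).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    window_days = (config.study_end - config.study_start).days

    case_ids = np.array([f"S{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.sex_female_fraction, "F", "M")
    age = rng.choice(_AGE_BANDS, size=n, p=_AGE_WEIGHTS)

    exposed = {
        spec.name: rng.random(n) < spec.exposure_prevalence for spec in config.drugs
    }
    # per-drug age overrides for exposed reports
    for spec in config.drugs:
        if spec.age_distribution:
            bands = list(spec.age_distribution)
            w = np.array([spec.age_distribution[b] for b in bands], dtype=float)
            w = w / w.sum()
            idx = np.flatnonzero(exposed[spec.name])
            age[idx] = rng.choice(bands, size=idx.size, p=w)

    odds = np.full(n, config.background_te_rate / (1 - config.background_te_rate))
    for spec in config.drugs:
        odds = np.where(exposed[spec.name], odds * spec.te_odds_multiplier, odds)
    is_te = rng.random(n) < odds / (1 + odds)

    report_year = rng.integers(config.study_start.year, config.study_end.year + 1, n)
    demo = pd.DataFrame(
        {
            "case_id": case_ids,
            "sex": sex,
            "age_category": age,
            "report_year": report_year,
        }
    )

    # --- drug table ----------------------------------------------------
    drug_frames = []
    start_day_by_drug: Dict[str, np.ndarray] = {}
    for spec in config.drugs:
        idx = np.flatnonzero(exposed[spec.name])
        start_days = rng.integers(0, window_days + 1, idx.size)
        start_day_by_drug[spec.name] = start_days
        drug_frames.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[idx],
                    "drug_name": spec.name,
                    "role_code": "suspected",
                    "start_date": _dates_to_iso(
                        start_days,
                        config.study_start,
                        rng,
                        config.partial_month_fraction,
                        config.partial_year_fraction,
                    ),
                    "end_date": "",
                }
            )
        )
    # every report carries one suspected background drug...
    bg = rng.choice(_BACKGROUND_DRUGS, size=n)
    bg_start = rng.integers(0, window_days + 1, n)
    drug_frames.append(
        pd.DataFrame(
            {
                "case_id": case_ids,
                "drug_name": bg,
                "role_code": "suspected",
                "start_date": _dates_to_iso(
                    bg_start,
                    config.study_start,
                    rng,
                    config.partial_month_fraction,
                    config.partial_year_fraction,
                ),
                "end_date": "",
            }
        )
    )
    # ... and ~30% an additional concomitant one (exercises role filtering)
    conc_idx = np.flatnonzero(rng.random(n) < 0.3)
    drug_frames.append(
        pd.DataFrame(
            {
                "case_id": case_ids[conc_idx],
                "drug_name": rng.choice(_BACKGROUND_DRUGS, size=conc_idx.size),
                "role_code": "concomitant",
                "start_date": "",
                "end_date": "",
            }
        )
    )
    drug_df = (
        pd.concat(drug_frames, ignore_index=True)
        .sort_values(["case_id", "role_code", "drug_name"], kind="stable")
        .reset_index(drop=True)
    )

    # --- reac table ----------------------------------------------------
    smq_pts = sorted(smq_pt_union(load_smq_terms()))
    pt_codes = np.empty(n, dtype=object)
    pt_names = np.empty(n, dtype=object)
    te_idx = np.flatnonzero(is_te)
    non_te_idx = np.flatnonzero(~is_te)
    pt_codes[te_idx] = rng.choice(smq_pts, size=te_idx.size)
    pt_names[te_idx] = "thromboembolic event"
    bg_pick = rng.integers(0, len(_BACKGROUND_PTS), non_te_idx.size)
    pt_codes[non_te_idx] = [_BACKGROUND_PTS[i][0] for i in bg_pick.tolist()]
    pt_names[non_te_idx] = [_BACKGROUND_PTS[i][1] for i in bg_pick.tolist()]

    # onset: default uniform in window; event cases exposed to a study drug
    # get start + Weibull(scale, shape) of the first exposed study drug
    onset_day = rng.integers(0, window_days + 1, n).astype(float)
    claimed = np.zeros(n, dtype=bool)
    durations_drawn: Dict[str, int] = {}
    for spec in config.drugs:
        idx = np.flatnonzero(exposed[spec.name] & is_te & ~claimed)
        claimed[idx] = True
        pos = {g: i for i, g in enumerate(np.flatnonzero(exposed[spec.name]))}
        starts = np.array([start_day_by_drug[spec.name][pos[g]] for g in idx])
        durations = np.round(
            spec.tto_scale_alpha * rng.weibull(spec.tto_shape_beta, idx.size)
        )
        onset_day[idx] = starts + durations
        durations_drawn[spec.name] = int(idx.size)
    reac = pd.DataFrame(
        {
            "case_id": case_ids,
            "pt_code": pt_codes,
            "pt_name": pt_names,
            "onset_date": _dates_to_iso(
                onset_day.astype(int),
                config.study_start,
                rng,
                config.partial_month_fraction,
                config.partial_year_fraction,
            ),
            "outcome": "unknown",
        }
    )

    # --- hist table ----------------------------------------------------
    hist_frames = []
    for term, prevalence in config.history_terms:
        idx = np.flatnonzero(rng.random(n) < prevalence)
        hist_frames.append(pd.DataFrame({"case_id": case_ids[idx], "term": term}))
    hist = (
        pd.concat(hist_frames, ignore_index=True)
        if hist_frames
        else pd.DataFrame(columns=["case_id", "term"])
    )
    hist = hist.sort_values(["case_id", "term"], kind="stable").reset_index(drop=True)

    # --- manifest ------------------------------------------------------
    n_te = int(is_te.sum())
    per_drug = {}
    for spec in config.drugs:
        e = exposed[spec.name]
        a = int((e & is_te).sum())
        b = int((e & ~is_te).sum())
        c = n_te - a
        d = n - n_te - b
        per_drug[spec.name] = {
            "config": dataclasses.asdict(spec),
            "realized": {
                "exposed": int(e.sum()),
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "ror": (a * d) / (b * c) if b * c > 0 else None,
                "n_te_durations": durations_drawn.get(spec.name, 0),
            },
        }
    manifest = {
        "seed": config.seed,
        "n_reports": n,
        "background_te_rate": config.background_te_rate,
        "realized_te_total": n_te,
        "drugs": per_drug,
    }
    tables = {"demo": demo, "drug": drug_df, "reac": reac, "hist": hist}
    return tables, manifest


def generate(config: SimConfig, outdir) -> Dict[str, Path]:
    """Write demo/drug/reac/hist CSVs plus ``manifest.json`` to ``outdir``."""
    tables, manifest = simulate_tables(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = mpath
    return paths


def plant_transactions(
    rules: Sequence[PlantedRule],
    n_transactions: int,
    n_te: int,
    te_item: str = TE_ITEM,
) -> List[Transaction]:
    """Lay out a transaction set with exactly the planted co-occurrences.

    Transactions 0..n_te-1 carry the event item; each rule's antecedent
    itemset occupies its own disjoint block (``n_with_te`` ids inside the
    event region, the rest outside), so realized counts equal planted
    counts exactly. Rules whose antecedents are subsets of one another
    would contaminate each other's counts and are rejected.
    """
    if n_te > n_transactions:
        raise UserInputError("n_te cannot exceed n_transactions")
    for i, r in enumerate(rules):
        for j, s in enumerate(rules):
            if i != j and set(r.antecedent_items) <= set(s.antecedent_items):
                raise UserInputError(
                    "planted antecedents must not be subsets of one another"
                )
    if sum(r.n_with_te for r in rules) > n_te:
        raise UserInputError("planted event co-occurrences exceed the event total")
    if sum(r.n_antecedent - r.n_with_te for r in rules) > n_transactions - n_te:
        raise UserInputError("planted antecedents exceed the non-event region")

    items: List[set] = [set() for _ in range(n_transactions)]
    for i in range(n_te):
        items[i].add(te_item)
    te_cursor, other_cursor = 0, n_te
    for r in rules:
        for _ in range(r.n_with_te):
            items[te_cursor].update(r.antecedent_items)
            te_cursor += 1
        for _ in range(r.n_antecedent - r.n_with_te):
            items[other_cursor].update(r.antecedent_items)
            other_cursor += 1
    return [
        Transaction(case_id=f"T{i:07d}", items=frozenset(s))
        for i, s in enumerate(items)
    ]


def write_transactions(transactions: Sequence[Transaction], path) -> Path:
    """Persist transactions as a ``case_id,items`` CSV (items ;-joined)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "case_id": [t.case_id for t in transactions],
            "items": ["; ".join(sorted(t.items)) for t in transactions],
        }
    )
    df.to_csv(path, index=False)
    return path
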