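"""End-to-end orchestration: simulate -> load -> signal -> tto -> mine.

A :class:`PipelineConfig` (round-trippable through YAML) drives the whole
chain and produces report-grade TSV outputs plus a structured run log in
which every filtering step reconciles (loaded = analysed + excluded,
per reason). Outputs are written atomically: everything is staged in a
temporary directory and moved into place only when every stage succeeded.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from ._util import UserInputError, round_half_up
from . import __version__
from .data import (
    flag_event_cases,
    load_smq_terms,
    read_tables,
)
from .disproportionality import DisproportionalityModel, two_way_frequency
from .mining import Apriori, MiningConfig
from .simulate import DrugSpec, SimConfig, generate
from .tto import compute_durations, fit_weibull, subgroup_analysis


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serialises to/from YAML."""

    input_dir: Optional[str] = None  # four-table directory; None -> simulate
    output_dir: str = "pvsignal-out"
    seed: int = 0
    drugs: List[str] = field(default_factory=list)
    combined_label: Optional[str] = "All study drugs"
    smq_path: Optional[str] = None  # None -> packaged thromboembolism SMQs
    strata: List[str] = field(
        default_factory=lambda: ["10-19", "20-29", "30-39", "40-49", "50-59"]
    )
    name_map: Dict[str, str] = field(default_factory=dict)
    min_support: float = 0.00001
    min_confidence: float = 0.9
    maxlen: int = 3
    include_age_item: bool = False
    tto_min_n: int = 10
    simulate: Optional[dict] = None  # SimConfig fields when input_dir is None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise UserInputError(f"config {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise UserInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        )

    def sim_config(self) -> SimConfig:
        raw = dict(self.simulate or {})
        drug_specs = [DrugSpec(**d) for d in raw.pop("drugs", [])]
        raw.setdefault("seed", self.seed)
        return SimConfig(drugs=drug_specs, **raw)


def run_pipeline(config: PipelineConfig) -> Dict[str, Path]:
    """Run every stage and write signal.tsv, tto.tsv, rules.tsv,
    frequency.tsv and run_log.json to the configured output directory."""
    outdir = Path(config.output_dir)
    staging = Path(tempfile.mkdtemp(prefix="pvsignal-"))
    try:
        paths = _run_stages(config, staging)
        outdir.mkdir(parents=True, exist_ok=True)
        final = {}
        for name, p in paths.items():
            dest = outdir / p.name
            shutil.move(str(p), dest)
            final[name] = dest
        return final
    finally:
        shutil.rmtree(staging, ignore_errors=True)


def _run_stages(config: PipelineConfig, staging: Path) -> Dict[str, Path]:
    log: Dict[str, object] = {"version": __version__, "seed": config.seed}

    if config.input_dir is None:
        sim = config.sim_config()
        data_dir = staging / "data"
        generate(sim, data_dir)
        log["simulated"] = {"n_reports": sim.n_reports, "seed": sim.seed}
        if not config.drugs:
            config = dataclasses.replace(
                config, drugs=[d.name for d in sim.drugs]
            )
    else:
        data_dir = Path(config.input_dir)

    smqs = load_smq_terms(config.smq_path)
    reports, load_report = read_tables(
        data_dir / "demo.csv",
        data_dir / "drug.csv",
        data_dir / "reac.csv",
        data_dir / "hist.csv",
        name_map=config.name_map or None,
    )
    n_te = flag_event_cases(reports, smqs)
    log["load"] = dataclasses.asdict(load_report)
    log["n_event_cases"] = n_te

    if not config.drugs:
        raise UserInputError("no study drugs configured")

    # --- signal --------------------------------------------------------
    model = DisproportionalityModel.from_reports(
        reports,
        config.drugs,
        strata=config.strata,
        combined_label=config.combined_label,
    )
    signal_df = model.fit().to_frame(rounded=True)
    log["signal"] = {
        "n_rows": len(signal_df),
        "exposures": {d: int(t.a + t.b) for d, t in model.tables.items()},
    }

    # --- time-to-onset -------------------------------------------------
    tto_rows, tto_log = [], {}
    all_records = []
    for drug in config.drugs:
        records, exclusions = compute_durations(reports, drug, smqs)
        all_records.extend(records)
        tto_log[drug] = {
            "analyzed": len(records),
            "excluded": exclusions,
            "loaded": len(records) + sum(exclusions.values()),
        }
        if records:
            fit = fit_weibull([r.duration for r in records], min_n=config.tto_min_n)
            q1, med, q3 = fit.quartiles
            tto_rows.append(
                {
                    "drug": drug,
                    "n": fit.n,
                    "median": round_half_up(med, 1),
                    "q1": round_half_up(q1, 1),
                    "q3": round_half_up(q3, 1),
                    "alpha": round_half_up(fit.alpha, 1) if fit.alpha else "",
                    "alpha_lo": round_half_up(fit.alpha_ci[0], 1) if fit.alpha_ci else "",
                    "alpha_hi": round_half_up(fit.alpha_ci[1], 1) if fit.alpha_ci else "",
                    "beta": round_half_up(fit.beta, 2) if fit.beta else "",
                    "beta_lo": round_half_up(fit.beta_ci[0], 2) if fit.beta_ci else "",
                    "beta_hi": round_half_up(fit.beta_ci[1], 2) if fit.beta_ci else "",
                    "hazard_class": fit.hazard_class.value,
                }
            )
    tto_df = pd.DataFrame(tto_rows)
    subgroup_df = subgroup_analysis(all_records, min_n=config.tto_min_n)
    log["tto"] = tto_log

    # --- mining --------------------------------------------------------
    mcfg = MiningConfig(
        min_support=config.min_support,
        min_confidence=config.min_confidence,
        maxlen=config.maxlen,
        include_age_item=config.include_age_item,
    )
    mining_results = Apriori.from_reports(reports, mcfg).fit()
    rules_df = mining_results.to_frame(rounded=True)
    log["mining"] = {
        "n_frequent_itemsets": len(mining_results.frequent_itemsets),
        "n_rules": len(mining_results.rules),
    }

    # --- two-way frequency (mosaic-plot table) -------------------------
    counts, props = two_way_frequency(reports)
    freq_df = counts.reset_index() if not counts.empty else pd.DataFrame()

    paths = {}
    for name, df in [
        ("signal", signal_df),
        ("tto", tto_df),
        ("tto_subgroups", subgroup_df),
        ("rules", rules_df),
        ("frequency", freq_df),
    ]:
        p = staging / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    log_path = staging / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    paths["run_log"] = log_path
    return paths


def reference_counts_path() -> Path:
    """Path of the packaged reference signal table (counts + published
    estimates for the combined estrogen-progestin / thromboembolism screen)."""
    ref = resources.files("pvsignal.datasets") / "cep_te_reference_counts.csv"
    with resources.as_file(ref) as p:
        return Path(p)


def replay_reference_screen(fixture_path=None) -> pd.DataFrame:
    """Recompute the full signal screen from the reference count margins.

    Each fixture row carries report-level margins (case, total, event
    total, database size); the screen statistics are recomputed from the
    reconstructed 2x2 tables. The returned frame has one row per fixture
    row with a ``stratum`` key matching the fixture's ``age_band``.
    """
    from .disproportionality import (
        ContingencyTable,
        DisproportionalityResults,
        evaluate_table,
    )

    fixture = pd.read_csv(fixture_path or reference_counts_path())
    rows = []
    for r in fixture.itertuples(index=False):
        t = ContingencyTable.from_margins(
            int(r.case), int(r.total), int(r.event_total), int(r.n_total)
        )
        rows.append(evaluate_table(str(r.drug), t, stratum=str(r.age_band)))
    return DisproportionalityResults(model=None, results=rows).to_frame(rounded=True)


def validate_against_fixture(
    results: pd.DataFrame,
    fixture: pd.DataFrame,
    keys: Sequence[str] = ("drug", "stratum"),
    tolerances: Optional[Dict[str, float]] = None,
) -> List[dict]:
    """Cell-by-cell comparison of computed results against expected values.

    Returns a machine-readable diff: one entry per mismatching cell
    (naming the key and column) or per missing row. An empty list means
    the results reproduce the fixture within tolerance.
    """
    if tolerances is None:
        tolerances = {
            "prr": 0.1, "prr_lo": 0.1, "prr_hi": 0.1,
            "ror": 0.1, "ror_lo": 0.1, "ror_hi": 0.1,
            "chi2": 0.3,
        }
    for k in keys:
        if k not in results.columns or k not in fixture.columns:
            raise UserInputError(f"key column {k!r} missing")
    diffs: List[dict] = []
    indexed = results.set_index(list(keys))
    for row in fixture.itertuples(index=False):
        key = tuple(getattr(row, k) for k in keys)
        if key not in indexed.index:
            diffs.append({"key": key, "column": None, "problem": "missing_row"})
            continue
        got = indexed.loc[key]
        for col, tol in tolerances.items():
            if col not in fixture.columns:
                continue
            expected = getattr(row, col)
            if pd.isna(expected) or expected == "":
                continue  # suppressed in the fixture
            value = got[col]
            try:
                value = float(value)
            except (TypeError, ValueError):
                diffs.append(
                    {"key": key, "column": col, "problem": "suppressed",
                     "expected": float(expected), "got": str(value)}
                )
                continue
            if abs(value - float(expected)) > tol + 1e-9:
                diffs.append(
                    {"key": key, "column": col, "problem": "mismatch",
                     "expected": float(expected), "got": value}
                )
    return diffs
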