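"""Shared fixtures: tiny handwritten four-table datasets and SMQ sets."""

from __future__ import annotations

import pandas as pd
import pytest

from pvsignal.data import load_smq_terms, read_tables, flag_event_cases


def write_tables_from_rows(tmpdir, demo, drug, reac, hist):
    """Write four CSVs from row-dict lists; returns the directory."""
    cols = {
        "demo": ["case_id", "sex", "age_category", "report_year"],
        "drug": ["case_id", "drug_name", "role_code", "start_date", "end_date"],
        "reac": ["case_id", "pt_code", "pt_name", "onset_date", "outcome"],
        "hist": ["case_id", "term"],
    }
    for name, rows in [("demo", demo), ("drug", drug), ("reac", reac), ("hist", hist)]:
        pd.DataFrame(rows, columns=cols[name]).to_csv(
            tmpdir / f"{name}.csv", index=False
        )
    return tmpdir


@pytest.fixture(scope="session")
def smqs():
    return load_smq_terms()


@pytest.fixture()
def toy_dataset(tmp_path):
    """Three reports: one TE case on the study drug (day-precision dates),
    one non-case on the study drug, one unexposed TE case."""
    demo = [
        {"case_id": "C1", "sex": "F", "age_category": "30-39", "report_year": 2012},
        {"case_id": "C2", "sex": "F", "age_category": "20-29", "report_year": 2011},
        {"case_id": "C3", "sex": "F", "age_category": "40-49", "report_year": 2013},
    ]
    drug = [
        {"case_id": "C1", "drug_name": "Drospirenone-EE", "role_code": "suspected",
         "start_date": "2010-01-01", "end_date": ""},
        {"case_id": "C1", "drug_name": "acetaminophen", "role_code": "concomitant",
         "start_date": "2010-02", "end_date": ""},
        {"case_id": "C2", "drug_name": "Drospirenone-EE", "role_code": "suspected",
         "start_date": "2011-05-04", "end_date": "2011-06-01"},
        {"case_id": "C3", "drug_name": "loxoprofen", "role_code": "suspected",
         "start_date": "2013", "end_date": ""},
    ]
    reac = [
        # pulmonary embolism: in the venous SMQ
        {"case_id": "C1", "pt_code": "10037377", "pt_name": "Pulmonary embolism",
         "onset_date": "2010-01-17", "outcome": "recovered"},
        {"case_id": "C2", "pt_code": "99000001", "pt_name": "Nausea",
         "onset_date": "2011-05-20", "outcome": "recovered"},
        # deep vein thrombosis, also venous SMQ
        {"case_id": "C3", "pt_code": "10051055", "pt_name": "Deep vein thrombosis",
         "onset_date": "2013-04-02", "outcome": "unknown"},
    ]
    hist = [
        {"case_id": "C1", "term": "dysmenorrhea"},
        {"case_id": "C1", "term": "smoking"},
        {"case_id": "C3", "term": "hypertension"},
    ]
    return write_tables_from_rows(tmp_path, demo, drug, reac, hist)


@pytest.fixture()
def toy_reports(toy_dataset, smqs):
    reports, load_report = read_tables(
        toy_dataset / "demo.csv",
        toy_dataset / "drug.csv",
        toy_dataset / "reac.csv",
        toy_dataset / "hist.csv",
    )
    flag_event_cases(reports, smqs)
    return reports, load_report
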