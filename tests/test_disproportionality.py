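"""Disproportionality statistics: 2x2 construction, ROR/PRR/chi2, flags."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import Table2x2

import pvsignal as pv
from pvsignal._util import UserInputError, round_half_up
from pvsignal.disproportionality import (
    ContingencyTable,
    Suppression,
    evaluate_table,
    two_way_frequency,
    yates_chi2,
)


class TestContingencyConstruction:
    def test_margins_rebuild_reference_cells(self):
        t = ContingencyTable.from_margins(744, 1163, 14593, 338224)
        assert (t.a, t.b, t.c, t.d) == (744, 419, 13849, 323212)
        assert t.n == 338224
        t2 = ContingencyTable.from_margins(237, 332, 14593, 338224)
        assert (t2.a, t2.b, t2.c, t2.d) == (237, 95, 14356, 323536)

    def test_empty_exposure_allowed(self):
        t = ContingencyTable.from_margins(0, 0, 10, 100)
        assert (t.a, t.b, t.c, t.d) == (0, 0, 10, 90)

    def test_negative_derived_cell_rejected(self):
        with pytest.raises(UserInputError):
            ContingencyTable.from_margins(50, 40, 100, 1000)


class TestEstimates:
    def test_ror_matches_reference_values(self):
        est = pv.compute_ror(ContingencyTable.from_margins(744, 1163, 14593, 338224))
        assert [round_half_up(v, 1) for v in est] == [41.4, 36.7, 46.8]
        est = pv.compute_ror(ContingencyTable.from_margins(237, 332, 14593, 338224))
        assert [round_half_up(v, 1) for v in est] == [56.2, 44.3, 71.4]

    def test_prr_matches_reference_values(self):
        est = pv.compute_prr(ContingencyTable.from_margins(744, 1163, 14593, 338224))
        assert [round_half_up(v, 1) for v in est] == [15.6, 13.8, 17.6]
        est = pv.compute_prr(ContingencyTable.from_margins(237, 332, 14593, 338224))
        assert [round_half_up(v, 1) for v in est] == [16.8, 13.2, 21.3]

    def test_independent_table_gives_unity(self):
        t = ContingencyTable(25, 25, 25, 25)
        ror = pv.compute_ror(t)
        prr = pv.compute_prr(t)
        assert ror[0] == prr[0] == 1.0
        assert ror[1] < 1 < ror[2]

    def test_exact_unity_whenever_ad_equals_bc(self):
        for t in [ContingencyTable(10, 90, 90, 810), ContingencyTable(3, 6, 7, 14)]:
            assert pv.compute_ror(t)[0] == pytest.approx(1.0)
            assert pv.compute_prr(t)[0] == pytest.approx(1.0)

    def test_yates_chi2_reference_and_clamp(self):
        assert yates_chi2(
            ContingencyTable.from_margins(744, 1163, 14593, 338224)
        ) == pytest.approx(10046.1, abs=0.2)
        assert yates_chi2(
            ContingencyTable.from_margins(237, 332, 14593, 338224)
        ) == pytest.approx(3604.9, abs=0.3)
        # exactly independent: correction clamps to zero
        assert yates_chi2(ContingencyTable(10, 90, 90, 810)) == 0.0

    def test_zero_cell_suppresses_not_raises(self):
        t = ContingencyTable(0, 5, 10, 100)
        assert pv.compute_ror(t) is None
        assert pv.compute_prr(t) is None

    def test_oracle_scipy_yates(self):
        """Independent route: scipy's continuity-corrected chi2 agrees."""
        for t in [
            ContingencyTable.from_margins(744, 1163, 14593, 338224),
            ContingencyTable(12, 34, 56, 78),
        ]:
            expected = chi2_contingency(
                np.array([[t.a, t.b], [t.c, t.d]]), correction=True
            ).statistic
            assert yates_chi2(t) == pytest.approx(expected, rel=1e-10)

    def test_oracle_statsmodels_odds_ratio(self):
        """Independent route: statsmodels Table2x2 odds ratio and Wald CI."""
        t = ContingencyTable.from_margins(198, 351, 14593, 338224)
        sm = Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        ror, lo, hi = pv.compute_ror(t)
        assert ror == pytest.approx(sm.oddsratio, rel=1e-12)
        smlo, smhi = sm.oddsratio_confint(alpha=0.05)
        assert lo == pytest.approx(smlo, rel=1e-9)
        assert hi == pytest.approx(smhi, rel=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 2000), d=st.integers(1, 20000),
    )
    def test_monotone_in_a(self, a, b, c, d):
        """Adding a case (holding other cells) strictly increases ROR and PRR."""
        t0, t1 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert pv.compute_ror(t1)[0] > pv.compute_ror(t0)[0]
        assert pv.compute_prr(t1)[0] > pv.compute_prr(t0)[0]


class TestSignalFlagsAndSuppression:
    def test_reference_row_raises_both_flags(self):
        r = evaluate_table("Dro-EE", ContingencyTable.from_margins(237, 332, 14593, 338224))
        assert r.ror_signal and r.prr_signal
        assert r.suppressed is Suppression.NONE
        assert r.reporting_ratio == pytest.approx(71.4, abs=0.05)

    def test_single_case_suppresses_ror_flag(self):
        r = evaluate_table("x", ContingencyTable(1, 1, 100, 100000))
        assert r.suppressed is Suppression.LT2_CASES
        assert r.ror is None and not r.ror_signal

    def test_two_cases_keep_ror_but_suppress_prr(self):
        # mirrors a published row with 2 cases: ROR shown, PRR/chi2 dashed
        r = evaluate_table("x", ContingencyTable.from_margins(2, 3, 14593, 338224))
        assert r.suppressed is Suppression.LT3_CASES
        assert round_half_up(r.ror, 1) == 44.4
        assert r.prr is None and r.chi2 is None and not r.prr_signal

    def test_no_noncase_suppresses_everything(self):
        r = evaluate_table("x", ContingencyTable.from_margins(2, 2, 14593, 338224))
        assert r.suppressed is Suppression.NO_NONCASE
        assert r.ror is None and r.prr is None and r.chi2 is None

    def test_prr_flag_needs_threshold(self):
        # large case count but weak disproportionality: no PRR signal
        r = evaluate_table("x", ContingencyTable(50, 1000, 5000, 100000))
        assert r.case_count == 50 and r.prr < 2 and not r.prr_signal


class TestFromReports:
    def test_counts_equal_brute_force_odds(self, toy_reports):
        """Dual route: table-based ROR equals odds computed by enumerating
        report lists directly."""
        reports, _ = toy_reports
        model = pv.DisproportionalityModel.from_reports(reports, ["Drospirenone-EE"])
        t = model.tables["Drospirenone-EE"]
        exposed = [
            r for r in reports.values()
            if any(d.drug_name == "drospirenone-ee" and d.role_code == "suspected"
                   for d in r.drugs)
        ]
        unexposed = [r for r in reports.values() if r not in exposed]
        a = sum(r.is_te for r in exposed)
        b = len(exposed) - a
        c = sum(r.is_te for r in unexposed)
        d = len(unexposed) - c
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d) == (1, 1, 1, 0)

    def test_stratified_comparator_is_full_database(self):
        """Replaying a stratum row must use c,d from the whole database."""
        t = ContingencyTable.from_margins(298, 400, 14593, 338224)
        assert [round_half_up(v, 1) for v in pv.compute_ror(t)] == [66.1, 52.8, 82.8]
        t = ContingencyTable.from_margins(14, 30, 14593, 338224)
        assert [round_half_up(v, 1) for v in pv.compute_ror(t)] == [19.4, 9.5, 39.8]


class TestTwoWayFrequency:
    def test_column_proportions_sum_to_one(self, toy_reports):
        reports, _ = toy_reports
        counts, props = two_way_frequency(reports)
        got = props.sum(axis=0)
        nonzero = counts.sum(axis=0) > 0
        assert np.allclose(got[nonzero], 1.0)

    def test_known_mixture_recovered(self):
        rng = np.random.default_rng(11)
        reports = {}
        for i in range(2000):
            age = "20-29" if rng.random() < 0.5 else "30-39"
            disease = "dysmenorrhea" if (
                rng.random() < (0.8 if age == "20-29" else 0.3)
            ) else "endometriosis"
            r = pv.CaseReport(
                f"C{i}",
                pv.DemoRecord(f"C{i}", "F", age, 2010),
                history=[pv.HistoryRecord(f"C{i}", disease)],
            )
            reports[f"C{i}"] = r
        _, props = two_way_frequency(reports)
        assert props.loc["dysmenorrhea", "20-29"] == pytest.approx(0.8, abs=0.05)
        assert props.loc["dysmenorrhea", "30-39"] == pytest.approx(0.3, abs=0.05)
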