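"""Disproportionality statistics: closed forms, oracles, criteria, screening."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    ContingencyTable,
    EventDefinition,
    SignalCriteria,
    compute_chi2,
    compute_ebgm,
    compute_ic,
    compute_prr,
    compute_ror,
    evaluate_signal,
    screen_event,
)
from pvsignal.stats import compute_signal
from .conftest import make_report

cells = st.integers(1, 500)
tables = st.builds(ContingencyTable, cells, cells, cells, cells)


class TestRor:
    def test_independence_table(self):
        r = compute_ror(ContingencyTable(10, 10, 10, 10))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_lower < 1.0 < r.ci_upper

    def test_hand_computed_point_and_ci(self):
        # ROR = (10*40)/(20*30); CI = exp(ln ROR +/- 1.96*sqrt(1/10+1/20+1/30+1/40))
        r = compute_ror(ContingencyTable(10, 20, 30, 40))
        assert r.ror == pytest.approx(2 / 3, rel=1e-12)
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40)
        assert r.ci_lower == pytest.approx((2 / 3) * math.exp(-1.959963984540054 * se), rel=1e-9)
        assert r.ci_upper == pytest.approx((2 / 3) * math.exp(+1.959963984540054 * se), rel=1e-9)

    def test_large_table_hand_value(self):
        assert compute_ror(ContingencyTable(10, 90, 100, 9900)).ror == pytest.approx(11.0)

    def test_zero_cell_flagged_not_raised(self):
        r = compute_ror(ContingencyTable(5, 0, 3, 7))
        assert not r.defined and math.isnan(r.ror)

    def test_continuity_correction_opt_in(self):
        r = compute_ror(ContingencyTable(5, 0, 3, 7), continuity_correction=True)
        assert r.defined
        assert r.ror == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tables)
    def test_matches_statsmodels_table2x2(self, t):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        tab = sm.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        r = compute_ror(t)
        assert r.ror == pytest.approx(tab.oddsratio, rel=1e-10)
        lo, hi = tab.oddsratio_confint(0.05)
        assert r.ci_lower == pytest.approx(lo, rel=1e-6)
        assert r.ci_upper == pytest.approx(hi, rel=1e-6)


class TestPrrChi2:
    def test_null_table_chi2_zero_prr_one(self):
        r = compute_prr(ContingencyTable(10, 10, 10, 10))
        assert r.chi2 == pytest.approx(0.0)
        assert r.prr == pytest.approx(1.0)

    def test_hand_computed_chi2(self):
        # (20*820-80*80)^2 * 1000 / (100*900*100*900)
        assert compute_chi2(ContingencyTable(20, 80, 80, 820)) == pytest.approx(12.3457, abs=1e-4)

    def test_hand_computed_prr(self):
        r = compute_prr(ContingencyTable(10, 20, 30, 40))
        assert r.prr == pytest.approx((10 / 30) / (30 / 70), rel=1e-12)

    def test_chi2_transpose_symmetry(self):
        t = ContingencyTable(7, 23, 41, 929)
        swapped = ContingencyTable(7, 41, 23, 929)
        assert compute_chi2(t) == pytest.approx(compute_chi2(swapped))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tables)
    def test_chi2_matches_scipy_uncorrected(self, t):
        scipy_stats = pytest.importorskip("scipy.stats")
        expected = scipy_stats.chi2_contingency(
            np.array([[t.a, t.b], [t.c, t.d]]), correction=False
        ).statistic
        assert compute_chi2(t) == pytest.approx(expected, rel=1e-10)


class TestIcEbgm:
    def test_independence_gives_ic_zero_ebgm_one(self):
        t = ContingencyTable(10, 90, 90, 810)  # a*N == (a+c)(a+b): 10*1000 == 100*100
        assert compute_ic(t).ic == pytest.approx(0.0, abs=1e-12)
        assert compute_ebgm(t).ebgm == pytest.approx(1.0)

    def test_hand_computed_ebgm(self):
        assert compute_ebgm(ContingencyTable(10, 90, 100, 9900)).ebgm == pytest.approx(
            10 * 10100 / (110 * 100), rel=1e-12
        )

    def test_ic025_closed_form(self):
        # ic025 = ic - 2/(ln2 * sqrt(a+1))
        t = ContingencyTable(56, 1000, 500, 100000)
        r = compute_ic(t)
        assert r.ic025 == pytest.approx(r.ic - 2 / (math.log(2) * math.sqrt(57)), rel=1e-12)

    def test_a_zero_flagged(self):
        assert not compute_ic(ContingencyTable(0, 5, 5, 5)).defined
        assert not compute_ebgm(ContingencyTable(0, 5, 5, 5)).defined

    def test_bate1998_dispersion_switch(self):
        t = ContingencyTable(50, 1000, 500, 100000)
        default = compute_ic(t)
        bate = compute_ic(t, ic_dispersion="bate1998")
        assert bate.ic == default.ic            # point estimate unchanged
        assert bate.ic025 != default.ic025      # dispersion differs
        assert bate.ic025 < bate.ic
        with pytest.raises(ValueError):
            compute_ic(t, ic_dispersion="nope")

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tables)
    def test_ic_is_log2_of_ebgm(self, t):
        """Both derive from a*N/((a+c)(a+b)); exact to machine precision."""
        assert compute_ic(t).ic == pytest.approx(math.log2(compute_ebgm(t).ebgm), abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(tables)
    def test_ror_at_least_prr_when_above_one(self, t):
        ror, prr = compute_ror(t).ror, compute_prr(t).prr
        if ror > 1:
            assert ror >= prr - 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(1, 50), st.integers(1, 200), st.integers(1, 200), st.integers(1, 5000))
    def test_ror_prr_strictly_increase_in_a(self, a, b, c, d):
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert compute_ror(t2).ror > compute_ror(t1).ror
        assert compute_prr(t2).prr > compute_prr(t1).prr

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(1, 50), st.integers(2, 200), st.integers(2, 200), st.integers(1, 5000))
    def test_all_four_increase_with_margins_fixed(self, a, b, c, d):
        """Shift one report from the off-diagonal into a, keeping all margins:
        every statistic strictly increases.  (With b, c, d held fixed instead,
        IC/EBGM are not monotone in a because N grows with a.)"""
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b - 1, c - 1, d + 1)
        assert compute_ror(t2).ror > compute_ror(t1).ror
        assert compute_prr(t2).prr > compute_prr(t1).prr
        assert compute_ic(t2).ic > compute_ic(t1).ic
        assert compute_ebgm(t2).ebgm > compute_ebgm(t1).ebgm


class TestCriteria:
    def test_min_a_gate_blocks_small_counts(self):
        t = ContingencyTable(2, 1, 1, 1000)  # huge ror but a < 3
        r = evaluate_signal(compute_signal("x", t))
        assert not r.ror_pos and not r.prr_pos

    def test_independence_not_a_signal(self):
        r = evaluate_signal(compute_signal("x", ContingencyTable(10, 10, 10, 10)))
        assert not r.signal

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 8), st.integers(1, 40), st.integers(1, 40), st.integers(50, 4000))
    def test_flags_match_inequality_reevaluation(self, a, b, c, d):
        """Brute-force re-evaluation of the four printed inequalities."""
        t = ContingencyTable(a, b, c, d)
        crit = SignalCriteria()
        r = evaluate_signal(compute_signal("x", t), crit)
        ror, prr, ic, ebgm = compute_ror(t), compute_prr(t), compute_ic(t), compute_ebgm(t)

        def ok(x):
            return not math.isnan(x)

        assert r.ror_pos == (a >= 3 and ok(ror.ci_lower) and ror.ci_lower > 1)
        assert r.prr_pos == (
            a >= 3 and ok(prr.ci_lower) and prr.ci_lower > 1 and prr.prr >= 2
        )
        assert r.bcpnn_pos == (ok(ic.ic025) and ic.ic025 > 0)
        assert r.mgps_pos == (ok(ebgm.ebgm05) and ebgm.ebgm05 > 2)
        assert r.signal == (r.ror_pos and r.prr_pos and r.bcpnn_pos and r.mgps_pos)


class TestScreening:
    def test_degenerate_single_drug_universe(self):
        """c = 0: undefined estimates flagged, no crash."""
        reports = [
            make_report(1, reactions=("Polycystic ovaries",), drugs=(("X", "PS"),)),
            make_report(2, reactions=("Rash",), drugs=(("X", "PS"),)),
        ]
        res = screen_event(reports, EventDefinition.of("Polycystic ovaries"))
        assert len(res) == 1
        assert math.isnan(res[0].ror) and not res[0].signal

    def test_no_event_cases_returns_empty(self):
        reports = [make_report(1, reactions=("Rash",), drugs=(("X", "PS"),))]
        assert screen_event(reports, EventDefinition.of("Polycystic ovaries")) == []

    def test_screening_is_deterministic(self, spiked_cohort):
        from pvsignal import deduplicate_reports

        kept, _ = deduplicate_reports(spiked_cohort.to_reports())
        event = EventDefinition.of(spiked_cohort.config.target_pt)
        r1 = screen_event(kept, event)
        r2 = screen_event(kept, event)
        assert [(r.drug, r.a, r.ror) for r in r1] == [(r.drug, r.a, r.ror) for r in r2]

    def test_ranked_by_count_then_ror(self, spiked_cohort):
        from pvsignal import deduplicate_reports

        kept, _ = deduplicate_reports(spiked_cohort.to_reports())
        res = screen_event(kept, EventDefinition.of(spiked_cohort.config.target_pt))
        keys = [(-r.a, -(r.ror if not math.isnan(r.ror) else float("-inf")), r.drug)
                for r in res]
        assert keys == sorted(keys)

    def test_spiked_drug_flagged(self, spiked_cohort):
        """The strongly associated drug is a signal; a is its truth count."""
        from pvsignal import deduplicate_reports

        kept, _ = deduplicate_reports(spiked_cohort.to_reports())
        res = screen_event(kept, EventDefinition.of(spiked_cohort.config.target_pt))
        by_name = {r.drug: r for r in res}
        truth = spiked_cohort.truth.marginals.per_drug
        assert by_name["OLANZAPINE"].signal
        assert by_name["OLANZAPINE"].a == truth["OLANZAPINE"].n_drug_event


class TestNullCalibration:
    def test_wald_ci_coverage_near_95_percent(self):
        """Over 600 null-model tables the ROR CI covers the true OR ~95%."""
        rng = np.random.default_rng(20240901)
        n, p_drug, p_event = 20_000, 0.05, 0.01
        covered = total = 0
        for _ in range(600):
            drug = rng.random(n) < p_drug
            event = rng.random(n) < p_event  # independent: true OR = 1
            a = int((drug & event).sum())
            b = int((drug & ~event).sum())
            c = int((~drug & event).sum())
            d = n - a - b - c
            r = compute_ror(ContingencyTable(a, b, c, d))
            if not r.defined:
                continue
            total += 1
            covered += r.ci_lower <= 1.0 <= r.ci_upper
        assert total > 550
        assert covered / total == pytest.approx(0.95, abs=0.03)

    def test_point_estimates_converge_to_null(self):
        """lambda = 1 at large N: ROR, PRR, EBGM near 1 and IC near 0."""
        rng = np.random.default_rng(7)
        n = 400_000
        drug = rng.random(n) < 0.05
        event = rng.random(n) < 0.01
        a = int((drug & event).sum()); b = int((drug & ~event).sum())
        c = int((~drug & event).sum()); d = n - a - b - c
        t = ContingencyTable(a, b, c, d)
        assert compute_ror(t).ror == pytest.approx(1.0, abs=0.15)
        assert compute_prr(t).prr == pytest.approx(1.0, abs=0.15)
        assert compute_ebgm(t).ebgm == pytest.approx(1.0, abs=0.15)
        assert compute_ic(t).ic == pytest.approx(0.0, abs=0.2)
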