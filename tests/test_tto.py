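"""Time-to-onset: calendar arithmetic, quantiles, binning, ECDF."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvsignal import (
    EventDefinition,
    FaersDate,
    OnsetRecord,
    bin_onsets,
    collect_onsets,
    cumulative_onset,
    onset_days,
    tto_summary,
)
from pvsignal.tto import BIN_LABELS, bin_label
from .conftest import make_report


def d(x):
    return FaersDate.parse(x)


class TestOnsetDays:
    def test_calendar_difference(self):
        assert onset_days(d(20200101), d(20200131)) == (30, "ok")

    def test_negative_excluded(self):
        assert onset_days(d(20200301), d(20200101)) == (None, "negative")

    def test_partial_excluded(self):
        assert onset_days(d(202001), d(20200131)) == (None, "partial")
        assert onset_days(d(20200101), d(2020)) == (None, "partial")

    def test_missing_and_invalid_excluded(self):
        assert onset_days(d(""), d(20200131)) == (None, "missing")
        assert onset_days(d(20200230), d(20200301)) == (None, "invalid")

    def test_same_day_is_zero(self):
        assert onset_days(d(20200101), d(20200101)) == (0, "ok")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.dates(min_value=np.datetime64("1990-01-01").item(),
                    max_value=np.datetime64("2030-12-31").item()),
           st.integers(0, 4000))
    def test_matches_numpy_datetime_oracle(self, start, delta):
        """Random date pairs against an independent calendar library."""
        end64 = np.datetime64(start) + np.timedelta64(delta, "D")
        start_i = int(start.strftime("%Y%m%d"))
        end_i = int(str(end64).replace("-", ""))
        days, reason = onset_days(d(start_i), d(end_i))
        assert reason == "ok"
        assert days == int((end64 - np.datetime64(start)) / np.timedelta64(1, "D"))


class TestQuantiles:
    def test_interpolated_quartiles_hand_example(self):
        recs = [OnsetRecord("X", i, v) for i, v in enumerate([10, 20, 30, 40])]
        s = tto_summary(recs)
        assert (s.q1, s.median, s.q3) == (17.5, 25.0, 32.5)

    def test_single_record(self):
        s = tto_summary([OnsetRecord("X", 1, 7)])
        assert s.q1 == s.median == s.q3 == 7

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            tto_summary([])

    def test_mixed_drugs_rejected(self):
        with pytest.raises(ValueError, match="multiple drugs"):
            tto_summary([OnsetRecord("X", 1, 1), OnsetRecord("Y", 2, 2)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 4000), min_size=1, max_size=60))
    def test_matches_numpy_linear_quantiles(self, days):
        recs = [OnsetRecord("X", i, v) for i, v in enumerate(days)]
        s = tto_summary(recs)
        q1, med, q3 = np.quantile(np.asarray(days, float), [0.25, 0.5, 0.75])
        assert (s.q1, s.median, s.q3) == pytest.approx((q1, med, q3))
        assert s.q1 <= s.median <= s.q3


class TestBins:
    def test_boundary_enumeration(self):
        recs = [OnsetRecord("X", i, v) for i, v in enumerate([0, 30, 31, 360, 361])]
        hist = bin_onsets(recs)
        assert hist["0-30"] == 2
        assert hist["31-60"] == 1
        assert hist["331-360"] == 1
        assert hist[">360"] == 1

    def test_empty_input_all_zero(self):
        hist = bin_onsets([])
        assert set(hist) == set(BIN_LABELS) and sum(hist.values()) == 0

    def test_labels_cover_thirteen_bins(self):
        assert len(BIN_LABELS) == 13
        assert BIN_LABELS[0] == "0-30" and BIN_LABELS[-1] == ">360"

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 2000), max_size=80))
    def test_conservation_and_single_bin_membership(self, days):
        recs = [OnsetRecord("X", i, v) for i, v in enumerate(days)]
        hist = bin_onsets(recs)
        assert sum(hist.values()) == len(days)
        for v in days:
            assert bin_label(v) in BIN_LABELS


class TestEcdf:
    def test_definition(self):
        recs = [OnsetRecord("X", i, v) for i, v in enumerate([5, 5, 10])]
        assert cumulative_onset(recs) == [(5, pytest.approx(2 / 3)), (10, pytest.approx(1.0))]

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=80))
    def test_monotone_and_ends_at_one(self, days):
        recs = [OnsetRecord("X", i, v) for i, v in enumerate(days)]
        curve = cumulative_onset(recs)
        fracs = [f for _, f in curve]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=80))
    def test_cross_consistency_with_median_and_bins(self, days):
        """ECDF at the median >= 0.5; ECDF at day 30 equals bin(0-30)/n."""
        recs = [OnsetRecord("X", i, v) for i, v in enumerate(days)]
        s = tto_summary(recs)
        curve = cumulative_onset(recs)
        at = lambda day: max((f for v, f in curve if v <= day), default=0.0)
        assert at(s.median) >= 0.5
        assert at(30) == pytest.approx(bin_onsets(recs)["0-30"] / len(days))


class TestCollectOnsets:
    def test_earliest_full_precision_ps_start_used(self):
        from pvsignal import DrugEntry, Report, ReportKey

        r = Report(
            key=ReportKey(1, 1, 20200601),
            event_dt=d(20200510),
            drugs=(
                DrugEntry("X", "PS", therapy_start=d(20200501)),
                DrugEntry("X", "PS", therapy_start=d(20200401)),
                DrugEntry("X", "C", therapy_start=d(20100101)),  # non-PS ignored
            ),
            reactions=("Polycystic ovaries",),
        )
        recs, excl = collect_onsets([r], EventDefinition.of("Polycystic ovaries"))
        assert excl == []
        assert recs[0].days == 39  # 2020-04-01 .. 2020-05-10

    def test_exclusion_reasons_recorded(self):
        from pvsignal import DrugEntry, Report, ReportKey

        r = Report(
            key=ReportKey(1, 1, 20200601),
            event_dt=d(20200101),
            drugs=(DrugEntry("X", "PS", therapy_start=d(202005)),),
            reactions=("Polycystic ovaries",),
        )
        recs, excl = collect_onsets([r], EventDefinition.of("Polycystic ovaries"))
        assert recs == [] and excl[0].reason == "partial"

    def test_median_recovered_from_generator(self):
        """Configured latency median is recovered through the full pipeline."""
        from pvsignal import DrugSpec, SynthConfig, deduplicate_reports, generate_cohort
        from pvsignal.tto import summarize_by_drug

        cfg = SynthConfig(
            n_reports=4000, seed=5, baseline_event_prob=0.25,
            missing_date_rate=0.0, duplicate_rate=0.0,
            drugs=(DrugSpec("Valproic acid", 0.5, lam=4.0, onset_median_days=900.0),),
        )
        cohort = generate_cohort(cfg)
        kept, _ = deduplicate_reports(cohort.to_reports())
        recs, _ = collect_onsets(kept, EventDefinition.of(cfg.target_pt),
                                 drugs={"VALPROIC ACID"})
        assert len(recs) > 400
        s = [x for x in summarize_by_drug(recs) if x.drug == "VALPROIC ACID"][0]
        assert s.median == pytest.approx(900, rel=0.15)
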