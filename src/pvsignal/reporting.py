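"""Descriptive summaries and study-style tabular exports.

Covers the descriptive side of a screening study — reports by year,
country, reporter occupation, age decade, weight band and outcome —
plus formatting of the ranked signal table, forest-plot data, and
time-to-onset tables as delimited text.

Denominator conventions (stated because source data leaves them open):
percentages for age, weight, reporter and outcome are over the total
number of event reports; a report carrying several outcome codes
contributes one mention to each code's count, so outcome percentages
may sum past 100.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .io import Report
from .stats import SignalResult
from .tto import TTOSummary, cumulative_onset, OnsetRecord

logger = logging.getLogger(__name__)

#: FAERS occupation codes -> reporter category.  Configurable because
#: published category labels do not map one-to-one onto the codes.
DEFAULT_REPORTER_MAP: dict[str, str] = {
    "CN": "Consumer",
    "MD": "Physician",
    "OT": "Other health-professional",
    "PH": "Pharmacist",
    "LW": "Lawyer",
}

#: Age-unit code -> factor converting to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 7 / 365.25,
    "DY": 1 / 365.25, "HR": 1 / 8766.0,
}

#: Weight-unit code -> factor converting to kilograms.
WEIGHT_UNIT_TO_KG: dict[str, float] = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 0.001}

UNKNOWN = "Unknown"


@dataclass
class DescriptiveSummary:
    """Category counts (and percents over total reports) for event cases."""

    n_reports: int
    by_year: dict[int, int] = field(default_factory=dict)
    by_country: dict[str, int] = field(default_factory=dict)
    by_reporter: dict[str, int] = field(default_factory=dict)
    by_age: dict[str, int] = field(default_factory=dict)
    by_weight: dict[str, int] = field(default_factory=dict)
    by_outcome: dict[str, int] = field(default_factory=dict)
    unknown_age_units: int = 0

    def percent(self, count: int) -> float:
        return 100.0 * count / self.n_reports if self.n_reports else math.nan


def age_in_years(age: Optional[float], age_cod: Optional[str]) -> Optional[float]:
    """Age converted to years, or None when missing/unconvertible."""
    if age is None:
        return None
    factor = AGE_UNIT_TO_YEARS.get((age_cod or "YR").upper())
    if factor is None:
        return None
    return age * factor


def age_bin(years: Optional[float]) -> str:
    if years is None or years < 0:
        return UNKNOWN
    if years >= 90:
        return "90+"
    decade = int(years // 10) * 10
    return f"{decade}-{decade + 9}"


def weight_in_kg(wt: Optional[float], wt_cod: Optional[str]) -> Optional[float]:
    if wt is None:
        return None
    factor = WEIGHT_UNIT_TO_KG.get((wt_cod or "KG").upper())
    if factor is None:
        return None
    return wt * factor


def weight_bin(kg: Optional[float]) -> str:
    if kg is None or kg < 0:
        return UNKNOWN
    if kg > 100:
        return ">100"
    band = int(kg // 10) * 10
    return f"{band}-{band + 9}"


def descriptive_summary(
    reports: Sequence[Report],
    reporter_map: Mapping[str, str] = DEFAULT_REPORTER_MAP,
) -> DescriptiveSummary:
    """Tabulate deduplicated, event-selected reports by category.

    Every report lands in exactly one age bin and one weight bin
    (Unknown included); outcome counts are per code mention.  Ages with
    an unrecognized unit code are binned Unknown and counted in
    ``unknown_age_units``.
    """
    s = DescriptiveSummary(n_reports=len(reports))
    for r in reports:
        year = r.event_dt.year if r.event_dt.year is not None else (
            r.key.fda_dt // 10000 if r.key.fda_dt else None
        )
        if year is not None:
            s.by_year[year] = s.by_year.get(year, 0) + 1
        country = r.country or UNKNOWN
        s.by_country[country] = s.by_country.get(country, 0) + 1
        occ = (r.occupation or "").upper()
        reporter = reporter_map.get(occ, UNKNOWN if not occ else "Other")
        s.by_reporter[reporter] = s.by_reporter.get(reporter, 0) + 1

        years = age_in_years(r.age, r.age_cod)
        if r.age is not None and years is None:
            s.unknown_age_units += 1
        bin_ = age_bin(years)
        s.by_age[bin_] = s.by_age.get(bin_, 0) + 1

        wbin = weight_bin(weight_in_kg(r.wt, r.wt_cod))
        s.by_weight[wbin] = s.by_weight.get(wbin, 0) + 1

        for code in set(r.outcomes):
            s.by_outcome[code] = s.by_outcome.get(code, 0) + 1
    if s.unknown_age_units:
        logger.warning("descriptive_summary: %d report(s) with unknown age-unit codes",
                       s.unknown_age_units)
    return s


def summary_frames(s: DescriptiveSummary) -> dict[str, pd.DataFrame]:
    """One tidy (category, count, percent) DataFrame per breakdown."""
    out = {}
    for name, mapping in (
        ("year", s.by_year), ("country", s.by_country), ("reporter", s.by_reporter),
        ("age", s.by_age), ("weight", s.by_weight), ("outcome", s.by_outcome),
    ):
        rows = sorted(mapping.items(), key=lambda kv: (-kv[1], str(kv[0])))
        out[name] = pd.DataFrame(
            [(k, v, round(s.percent(v), 2)) for k, v in rows],
            columns=["category", "count", "percent"],
        )
    return out


# ---------------------------------------------------------------------------
# Signal-table exports
# ---------------------------------------------------------------------------

def _fmt(x: float, nd: int = 2) -> str:
    return "NA" if math.isnan(x) else f"{x:.{nd}f}"


def format_signal_table(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Study-style display table: Drug, Number, ROR (95%CI), PRR (χ2), EBGM (EBGM05), IC (IC025)."""
    rows = []
    for r in results:
        rows.append({
            "Drug": r.drug.title(),
            "Number": r.a,
            "ROR (95%CI)": f"{_fmt(r.ror)} ({_fmt(r.ror_ci[0])} - {_fmt(r.ror_ci[1])})",
            "PRR (chi2)": f"{_fmt(r.prr)} ({_fmt(r.chi2)})",
            "EBGM (EBGM05)": f"{_fmt(r.ebgm)} ({_fmt(r.ebgm05)})",
            "IC (IC025)": f"{_fmt(r.ic)} ({_fmt(r.ic025)})",
            "Signal": "Yes" if r.signal else "No",
        })
    return pd.DataFrame(rows)


def signal_table_full(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Machine-readable full-precision export with per-algorithm flags."""
    rows = []
    for r in results:
        rows.append({
            "drug": r.drug, "a": r.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.ror, "ror_lower": r.ror_ci[0], "ror_upper": r.ror_ci[1],
            "prr": r.prr, "prr_lower": r.prr_ci[0], "prr_upper": r.prr_ci[1],
            "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05,
            "ror_pos": r.ror_pos, "prr_pos": r.prr_pos,
            "bcpnn_pos": r.bcpnn_pos, "mgps_pos": r.mgps_pos, "signal": r.signal,
        })
    return pd.DataFrame(rows)


def forest_plot_data(results: Sequence[SignalResult]) -> pd.DataFrame:
    """Forest-plot export: ROR with CI bounds and log10 positions per drug."""
    rows = []
    for r in results:
        if math.isnan(r.ror):
            continue
        rows.append({
            "drug": r.drug, "ror": r.ror,
            "ci_lower": r.ror_ci[0], "ci_upper": r.ror_ci[1],
            "log10_ror": math.log10(r.ror),
            "log10_lower": math.log10(r.ror_ci[0]) if r.ror_ci[0] > 0 else math.nan,
            "log10_upper": math.log10(r.ror_ci[1]) if r.ror_ci[1] > 0 else math.nan,
        })
    return pd.DataFrame(rows)


def tto_table(summaries: Sequence[TTOSummary]) -> pd.DataFrame:
    """Per-drug latency table: n, median, Q1, Q3 (days)."""
    return pd.DataFrame(
        [
            {"Drug": s.drug.title(), "n": s.n, "Median (day)": s.median,
             "Q1 (day)": s.q1, "Q3 (day)": s.q3}
            for s in summaries
        ]
    )


def ecdf_table(records_by_drug: Mapping[str, Sequence[OnsetRecord]]) -> pd.DataFrame:
    """Long-format cumulative-onset export (drug, days, cumulative_fraction)."""
    rows = []
    for drug, records in records_by_drug.items():
        for day, frac in cumulative_onset(list(records)):
            rows.append({"drug": drug, "days": day, "cumulative_fraction": frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run metadata
# ---------------------------------------------------------------------------

def write_run_metadata(
    path: str | Path,
    *,
    inputs: Mapping[str, object],
    config: Mapping[str, object],
    attrition: Mapping[str, object] = (),
) -> None:
    """JSON sidecar recording inputs, a config hash, and filter attrition."""
    config_json = json.dumps(dict(config), sort_keys=True, default=str)
    payload = {
        "inputs": dict(inputs),
        "config": dict(config),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "attrition": dict(attrition),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
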