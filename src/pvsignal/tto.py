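"""Time-to-onset (latency) analysis.

Latency is the calendar-day difference between the start of therapy
with a primary-suspect drug and the adverse-event onset date recorded
on the report.  Only day-precision dates enter the arithmetic; partial,
invalid, missing or negative differences are excluded with a recorded
reason, so attrition is auditable.

Summaries per drug are median/Q1/Q3 with linear interpolation between
order statistics (position ``h = (n−1)·p``), a fixed 30-day histogram
``0–30, 31–60, …, 331–360, >360``, and an empirical cumulative onset
curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cases import EventDefinition
from .io import FaersDate, Report

#: Exclusion reasons for non-computable onset differences.
EXCLUDE_NEGATIVE = "negative"
EXCLUDE_PARTIAL = "partial"
EXCLUDE_INVALID = "invalid"
EXCLUDE_MISSING = "missing"

#: Histogram bin labels: 0..30 inclusive, then 31..60, …, 331..360, >360.
BIN_LABELS: tuple[str, ...] = (
    ("0-30",) + tuple(f"{lo}-{lo + 29}" for lo in range(31, 360, 30)) + (">360",)
)


@dataclass(frozen=True)
class OnsetRecord:
    """One computable drug/report latency, in whole days (>= 0)."""

    drug: str
    primaryid: int
    days: int


@dataclass(frozen=True)
class OnsetExclusion:
    """A drug/report pair excluded from latency analysis, with the reason."""

    drug: str
    primaryid: int
    reason: str


@dataclass(frozen=True)
class TTOSummary:
    """Per-drug latency summary: interpolated quartiles plus the binned histogram."""

    drug: str
    n: int
    median: float
    q1: float
    q3: float
    bins: dict[str, int]


def onset_days(therapy_start: FaersDate, event_dt: FaersDate) -> tuple[Optional[int], str]:
    """Calendar-day difference event − start, or the exclusion reason.

    Returns ``(days, "ok")`` when both dates are valid day-precision
    and the difference is non-negative; otherwise ``(None, reason)``
    with reason ``"missing"``, ``"invalid"``, ``"partial"`` or
    ``"negative"``.
    """
    for d in (therapy_start, event_dt):
        if d.precision == "missing":
            return None, EXCLUDE_MISSING
        if d.precision == "invalid":
            return None, EXCLUDE_INVALID
        if d.precision in ("month", "year"):
            return None, EXCLUDE_PARTIAL
    delta = (event_dt.as_date() - therapy_start.as_date()).days
    if delta < 0:
        return None, EXCLUDE_NEGATIVE
    return delta, "ok"


def collect_onsets(
    reports: Sequence[Report],
    event: EventDefinition,
    *,
    drugs: Optional[set[str]] = None,
) -> tuple[list[OnsetRecord], list[OnsetExclusion]]:
    """Latency records for the event cases' primary-suspect drugs.

    For each event report and each distinct PS drug name on it, the
    exposure origin is the *earliest* full-precision therapy start among
    that drug's PS entries; latency is the report's onset date minus
    that origin.  ``drugs`` optionally restricts to a set of normalized
    names.
    """
    records: list[OnsetRecord] = []
    excluded: list[OnsetExclusion] = []
    for r in reports:
        if not event.matches(r.reactions):
            continue
        for name in r.primary_suspect_names():
            if drugs is not None and name not in drugs:
                continue
            starts = [
                e.therapy_start for e in r.drugs
                if e.role == "PS" and e.drugname == name
            ]
            full = [s for s in starts if s.is_full]
            if full:
                origin = min(full, key=lambda s: s.raw)
            else:
                # fall back to the first start so the exclusion reason
                # reflects what the data actually contained
                origin = starts[0]
            days, reason = onset_days(origin, r.event_dt)
            if days is None:
                excluded.append(OnsetExclusion(name, r.key.primaryid, reason))
            else:
                records.append(OnsetRecord(name, r.key.primaryid, days))
    return records, excluded


def _interp_quantile(sorted_days: np.ndarray, p: float) -> float:
    # position h = (n-1)p, linear interpolation between order statistics
    h = (len(sorted_days) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(sorted_days) - 1)
    return float(sorted_days[lo] + (h - lo) * (sorted_days[hi] - sorted_days[lo]))


def bin_label(days: int) -> str:
    """The 30-day histogram bin for one latency value.

    Day 0–30 inclusive fall in the first bin, 31–60 in the second, and
    anything beyond 360 in the open top bin.
    """
    if days <= 30:
        return BIN_LABELS[0]
    if days > 360:
        return BIN_LABELS[-1]
    idx = (days - 31) // 30 + 1
    return BIN_LABELS[idx]


def bin_onsets(records: Sequence[OnsetRecord]) -> dict[str, int]:
    """Histogram of latencies over the fixed 30-day bins (all labels present)."""
    hist = {label: 0 for label in BIN_LABELS}
    for rec in records:
        hist[bin_label(rec.days)] += 1
    return hist


def tto_summary(records: Sequence[OnsetRecord]) -> TTOSummary:
    """Quartiles and histogram for one drug's latency records.

    All records must share one drug name; raises on empty input.
    """
    if not records:
        raise ValueError("tto_summary requires at least one record")
    names = {r.drug for r in records}
    if len(names) > 1:
        raise ValueError(f"records span multiple drugs: {sorted(names)}")
    days = np.sort(np.asarray([r.days for r in records], dtype=float))
    return TTOSummary(
        drug=records[0].drug,
        n=len(records),
        median=_interp_quantile(days, 0.50),
        q1=_interp_quantile(days, 0.25),
        q3=_interp_quantile(days, 0.75),
        bins=bin_onsets(records),
    )


def summarize_by_drug(records: Sequence[OnsetRecord]) -> list[TTOSummary]:
    """One :class:`TTOSummary` per drug, ordered by n desc then name."""
    by_drug: dict[str, list[OnsetRecord]] = {}
    for rec in records:
        by_drug.setdefault(rec.drug, []).append(rec)
    summaries = [tto_summary(recs) for recs in by_drug.values()]
    summaries.sort(key=lambda s: (-s.n, s.drug))
    return summaries


def cumulative_onset(records: Sequence[OnsetRecord]) -> list[tuple[int, float]]:
    """Empirical cumulative onset curve: (days, fraction with latency ≤ days).

    One point per distinct latency value, ending at 1.0.
    """
    if not records:
        return []
    days = np.sort(np.asarray([r.days for r in records]))
    values, counts = np.unique(days, return_counts=True)
    cum = np.cumsum(counts) / len(days)
    return [(int(v), float(f)) for v, f in zip(values, cum)]
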