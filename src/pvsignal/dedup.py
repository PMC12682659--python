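"""Case-level deduplication of FAERS report versions.

FAERS re-publishes a case every time its report is amended, so one
CASEID typically maps to several PRIMARYID versions.  Per FDA guidance,
analyses keep exactly one version per case: the one with the latest FDA
receipt date, breaking ties by the highest PRIMARYID.  Both stated tie
rules reduce to a lexicographic maximum on ``(fda_dt, primaryid)``.

Deduplication runs on bare :class:`~pvsignal.io.ReportKey` triples,
before any table joins, and emits an auditable decision per key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import Report, ReportKey, write_ascii_table

logger = logging.getLogger(__name__)

#: Retention reasons, in decreasing specificity.
REASON_ONLY = "only_version"
REASON_LATEST = "latest_fda_dt"
REASON_HIGHEST = "highest_primaryid"


@dataclass(frozen=True)
class DedupDecision:
    """The fate of one report version: retained or deleted, and why.

    ``reason`` is set for retained keys (``only_version`` when the case
    had a single version, ``latest_fda_dt`` when the receipt date alone
    decided, ``highest_primaryid`` when the date was tied); deleted keys
    carry the reason of the version that beat them.
    """

    key: ReportKey
    retained: bool
    reason: str


def _sort_value(key: ReportKey) -> tuple[int, int]:
    # Missing fda_dt sorts earliest: never retained unless only version.
    fda = key.fda_dt if key.fda_dt is not None else -1
    return (fda, key.primaryid)


def deduplicate(keys: Iterable[ReportKey]) -> list[DedupDecision]:
    """Choose one surviving version per CASEID.

    Within each caseid group the key with maximal ``(fda_dt,
    primaryid)`` is retained; all others are marked deleted.  Keys with
    missing ``fda_dt`` sort as earliest (a warning is logged).  Output
    is sorted by ``(caseid, primaryid)`` and therefore independent of
    input order.
    """
    groups: dict[int, list[ReportKey]] = {}
    n_missing = 0
    for k in keys:
        groups.setdefault(k.caseid, []).append(k)
        if k.fda_dt is None:
            n_missing += 1
    if n_missing:
        logger.warning("deduplicate: %d key(s) with missing fda_dt sort as earliest", n_missing)

    decisions: list[DedupDecision] = []
    for caseid in sorted(groups):
        group = groups[caseid]
        if len(group) == 1:
            decisions.append(DedupDecision(group[0], True, REASON_ONLY))
            continue
        winner = max(group, key=_sort_value)
        date_ties = sum(1 for k in group if k.fda_dt == winner.fda_dt)
        reason = REASON_HIGHEST if date_ties > 1 else REASON_LATEST
        for k in sorted(group, key=lambda k: k.primaryid):
            decisions.append(DedupDecision(k, k is winner, reason))
    return decisions


def retained_keys(decisions: Sequence[DedupDecision]) -> list[ReportKey]:
    """The surviving keys, in decision order."""
    return [d.key for d in decisions if d.retained]


def deduplicate_reports(reports: Sequence[Report]) -> tuple[list[Report], list[DedupDecision]]:
    """Apply the key rule to assembled reports; keep survivors in input order."""
    decisions = deduplicate(r.key for r in reports)
    keep = {d.key.primaryid for d in decisions if d.retained}
    return [r for r in reports if r.key.primaryid in keep], decisions


def write_audit_log(decisions: Sequence[DedupDecision], path: str | Path) -> None:
    """Write a delimited audit log mirroring the retain/delete decision per version."""
    write_ascii_table(
        path,
        ("caseid", "fda_dt", "primaryid", "delete", "reason"),
        (
            (d.key.caseid, d.key.fda_dt, d.key.primaryid,
             "No" if d.retained else "Yes", d.reason)
            for d in decisions
        ),
    )
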