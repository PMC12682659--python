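"""Target-event case selection and contingency-table marginals.

An adverse event of interest is defined by a list of MedDRA preferred
terms (PTs), matched exactly after case-folding — no dictionary
hierarchy traversal.  A deduplicated report is an event case iff any of
its reaction PTs matches.  Only drugs in the primary-suspect (PS) role
enter drug–event counting; secondary-suspect, concomitant and
interacting entries are excluded.

All counting is at report level: a report contributes at most once per
distinct PS drug name, and the denominator universe is every
deduplicated report in the study window (event and non-event alike),
which is what the ``d`` cell of the 2×2 table requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import Report


@dataclass(frozen=True)
class EventDefinition:
    """The target adverse event as a list of preferred-term strings."""

    pt_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.pt_terms:
            raise ValueError("pt_terms must be non-empty")
        if any(not t.strip() for t in self.pt_terms):
            raise ValueError("pt_terms must not contain empty strings")
        object.__setattr__(
            self, "_folded", frozenset(t.strip().casefold() for t in self.pt_terms)
        )

    @classmethod
    def of(cls, *terms: str) -> "EventDefinition":
        return cls(tuple(terms))

    def matches(self, reactions: Iterable[str]) -> bool:
        folded: frozenset[str] = self._folded  # type: ignore[attr-defined]
        return any(pt.strip().casefold() in folded for pt in reactions)


@dataclass(frozen=True)
class DrugMarginal:
    """Per-drug report counts: ``n_drug`` = a+b, ``n_drug_event`` = a."""

    n_drug: int
    n_drug_event: int


@dataclass
class MarginalCounts:
    """The marginal counts that populate every drug's 2×2 table.

    ``n_total`` is N (all deduplicated reports), ``n_event`` is a+c
    (reports carrying the target event), and ``per_drug`` maps each
    normalized PS drug name to its (a+b, a) pair.
    """

    n_total: int
    n_event: int
    per_drug: dict[str, DrugMarginal] = field(default_factory=dict)

    def validate(self) -> None:
        for name, m in self.per_drug.items():
            if not (0 <= m.n_drug_event <= min(m.n_drug, self.n_event)):
                raise ValueError(f"inconsistent marginals for {name!r}: {m}")
            if m.n_drug > self.n_total:
                raise ValueError(f"n_drug > n_total for {name!r}")


def select_event_cases(reports: Sequence[Report], event: EventDefinition) -> set[int]:
    """Primaryids of reports whose reactions match the event definition."""
    return {r.key.primaryid for r in reports if event.matches(r.reactions)}


def extract_primary_suspect_pairs(
    reports: Sequence[Report], case_ids: set[int]
) -> list[tuple[str, int]]:
    """(drugname, primaryid) pairs for PS drugs of the selected cases.

    One pair per distinct PS drug name within a report; a report with
    two PS entries of the same name yields a single pair, while two
    distinct PS drugs yield two.  Reports without PS drugs contribute
    nothing.
    """
    pairs: list[tuple[str, int]] = []
    for r in reports:
        if r.key.primaryid not in case_ids:
            continue
        for name in r.primary_suspect_names():
            pairs.append((name, r.key.primaryid))
    return pairs


def count_marginals(reports: Sequence[Report], event: EventDefinition) -> MarginalCounts:
    """Count N, a+c and each drug's (a+b, a) over deduplicated reports.

    Non-event reports contribute to a drug's ``n_drug`` (hence to its
    b cell) under the same PS-role filter.
    """
    counts = MarginalCounts(n_total=len(reports), n_event=0)
    for r in reports:
        is_event = event.matches(r.reactions)
        if is_event:
            counts.n_event += 1
        for name in r.primary_suspect_names():
            m = counts.per_drug.get(name)
            if m is None:
                m = DrugMarginal(0, 0)
            counts.per_drug[name] = DrugMarginal(
                m.n_drug + 1, m.n_drug_event + (1 if is_event else 0)
            )
    counts.validate()
    return counts
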