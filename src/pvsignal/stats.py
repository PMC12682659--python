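"""Disproportionality statistics and signal criteria for 2×2 tables.

For each drug–event pair the spontaneous-report database is collapsed
to a 2×2 contingency table::

                     target event   other events
    target drug           a              b
    other drugs           c              d

Four families of measures are computed on that table:

* **ROR** (reporting odds ratio): ``ad/bc`` with a Wald 95% CI on the
  log scale, ``exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))``.
* **PRR** (proportional reporting ratio):
  ``[a/(a+b)] / [c/(c+d)]`` with CI
  ``exp(ln PRR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))`` and the
  uncorrected Pearson χ² statistic
  ``(ad−bc)²·N / [(a+b)(c+d)(a+c)(b+d)]``.
* **IC** (information component, BCPNN family):
  ``log2[a·N / ((a+c)(a+b))]``, i.e. the log2 observed-to-expected
  ratio, with lower bound ``IC025 = IC − 2·SD``.  The dispersion used
  by default is the closed form ``SD(IC) = 1/(ln2·√(a+1))``, which
  reproduces published (IC, IC025) pairs across a = 4…56 to the printed
  precision; the full Bate-1998 Beta/Dirichlet posterior variance is
  available via ``ic_dispersion="bate1998"``.
* **EBGM**: here the *unshrunk* observed-to-expected reporting ratio
  ``a·N/((a+c)(a+b))`` (identical to ``2**IC``), with
  ``EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d))``.  A true
  gamma-Poisson shrinkage estimator is deliberately out of scope.

A drug–event pair is a *signal* when all four criteria hold
simultaneously: a ≥ 3 with ROR 95% CI lower bound > 1; a ≥ 3 with
PRR ≥ 2 and PRR CI lower bound > 1; IC025 > 0; EBGM05 > 2.

Zero cells: no continuity correction is applied by default; estimates
whose closed form divides by zero are returned as NaN with
``defined=False`` and fail their criterion.  An optional
Haldane–Anscombe 0.5 correction is opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

from .cases import EventDefinition, MarginalCounts, count_marginals
from .io import Report

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = math.log(2.0)

NAN = float("nan")


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts a, b, c, d for one drug–event pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_marginals(
        cls, n_total: int, n_event: int, n_drug: int, n_drug_event: int
    ) -> "ContingencyTable":
        """Build a table from (N, a+c, a+b, a)."""
        a = n_drug_event
        b = n_drug - a
        c = n_event - a
        d = n_total - a - b - c
        return cls(a, b, c, d)

    def corrected(self, delta: float = 0.5) -> "_FloatTable":
        """Haldane–Anscombe style table with ``delta`` added to every cell."""
        return _FloatTable(self.a + delta, self.b + delta, self.c + delta, self.d + delta)


class _FloatTable(NamedTuple):
    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


class RorResult(NamedTuple):
    ror: float
    ci_lower: float
    ci_upper: float
    defined: bool


class PrrResult(NamedTuple):
    prr: float
    ci_lower: float
    ci_upper: float
    chi2: float
    defined: bool


class IcResult(NamedTuple):
    ic: float
    ic025: float
    defined: bool


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float
    defined: bool


def compute_ror(t: ContingencyTable, *, continuity_correction: bool = False) -> RorResult:
    """Reporting odds ratio ``ad/bc`` with Wald 95% CI.

    Undefined (``defined=False``, NaN values) when any cell is zero,
    unless the optional 0.5 continuity correction is requested.
    """
    ft = t.corrected() if continuity_correction else t
    if min(ft.a, ft.b, ft.c, ft.d) <= 0:
        return RorResult(NAN, NAN, NAN, False)
    ror = (ft.a * ft.d) / (ft.b * ft.c)
    se = math.sqrt(1 / ft.a + 1 / ft.b + 1 / ft.c + 1 / ft.d)
    return RorResult(
        ror, math.exp(math.log(ror) - _Z95 * se), math.exp(math.log(ror) + _Z95 * se), True
    )


def compute_chi2(t: ContingencyTable) -> float:
    """Pearson χ² on the 2×2 table, no Yates correction.

    ``(ad−bc)²·N / [(a+b)(c+d)(a+c)(b+d)]``; NaN when any margin is zero.
    """
    margins = (t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d)
    if min(margins) == 0:
        return NAN
    num = (t.a * t.d - t.b * t.c) ** 2 * t.n
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return num / den


def compute_prr(t: ContingencyTable, *, continuity_correction: bool = False) -> PrrResult:
    """Proportional reporting ratio with 95% CI and Pearson χ²."""
    chi2 = compute_chi2(t)
    ft = t.corrected() if continuity_correction else t
    if ft.a <= 0 or ft.c <= 0 or (ft.c + ft.d) <= 0:
        return PrrResult(NAN, NAN, NAN, chi2, False)
    prr = (ft.a / (ft.a + ft.b)) / (ft.c / (ft.c + ft.d))
    var = 1 / ft.a - 1 / (ft.a + ft.b) + 1 / ft.c - 1 / (ft.c + ft.d)
    se = math.sqrt(max(var, 0.0))
    return PrrResult(
        prr, math.exp(math.log(prr) - _Z95 * se), math.exp(math.log(prr) + _Z95 * se),
        chi2, True,
    )


def _ic_sd_closed_form(a: int) -> float:
    return 1.0 / (_LN2 * math.sqrt(a + 1.0))


def _ic_sd_bate1998(t: ContingencyTable) -> float:
    """Posterior SD of the IC under the Bate (1998) Beta/Dirichlet model."""
    a, n = float(t.a), float(t.n)
    row, col = float(t.a + t.b), float(t.a + t.c)
    alpha = beta = 2.0
    alpha1 = beta1 = 1.0
    g11 = 1.0
    gamma = g11 * (n + alpha) * (n + beta) / ((row + alpha1) * (col + beta1))
    var = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - row + alpha - alpha1) / ((row + alpha1) * (1 + n + alpha))
        + (n - col + beta - beta1) / ((col + beta1) * (1 + n + beta))
    ) / (_LN2 ** 2)
    return math.sqrt(var)


def compute_ic(t: ContingencyTable, *, ic_dispersion: str = "closed_form") -> IcResult:
    """Information component ``log2[a·N/((a+c)(a+b))]`` and its lower bound.

    ``ic025 = ic − 2·SD``.  ``ic_dispersion`` selects the SD:
    ``"closed_form"`` (default) uses ``1/(ln2·√(a+1))``;
    ``"bate1998"`` uses the BCPNN posterior variance.
    """
    if t.a <= 0 or (t.a + t.c) == 0 or (t.a + t.b) == 0:
        return IcResult(NAN, NAN, False)
    ic = math.log2(t.a * t.n / ((t.a + t.c) * (t.a + t.b)))
    if ic_dispersion == "closed_form":
        sd = _ic_sd_closed_form(t.a)
    elif ic_dispersion == "bate1998":
        sd = _ic_sd_bate1998(t)
    else:
        raise ValueError(f"unknown ic_dispersion {ic_dispersion!r}")
    return IcResult(ic, ic - 2.0 * sd, True)


def compute_ebgm(t: ContingencyTable) -> EbgmResult:
    """Observed-to-expected reporting ratio ``a·N/((a+c)(a+b))`` and EBGM05.

    The point estimate is unshrunk (equal to ``2**IC`` on the same
    table); the lower bound uses the same log-scale SE as the ROR:
    ``EBGM05 = exp(ln EBGM − 1.96·√(1/a+1/b+1/c+1/d))``.
    """
    if t.a <= 0 or (t.a + t.c) == 0 or (t.a + t.b) == 0:
        return EbgmResult(NAN, NAN, False)
    ebgm = t.a * t.n / ((t.a + t.c) * (t.a + t.b))
    if min(t.b, t.c, t.d) <= 0:
        return EbgmResult(ebgm, NAN, True)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return EbgmResult(ebgm, math.exp(math.log(ebgm) - _Z95 * se), True)


@dataclass(frozen=True)
class SignalCriteria:
    """Positivity thresholds for the four algorithms (all configurable)."""

    min_a: int = 3
    ror_lower_gt: float = 1.0
    prr_min: float = 2.0
    prr_lower_gt: float = 1.0
    ic_lower_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class SignalResult:
    """All four statistics, interval bounds and criterion flags for one drug."""

    drug: str
    a: int
    table: ContingencyTable
    ror: float = NAN
    ror_ci: tuple[float, float] = (NAN, NAN)
    prr: float = NAN
    prr_ci: tuple[float, float] = (NAN, NAN)
    chi2: float = NAN
    ic: float = NAN
    ic025: float = NAN
    ebgm: float = NAN
    ebgm05: float = NAN
    ror_pos: bool = False
    prr_pos: bool = False
    bcpnn_pos: bool = False
    mgps_pos: bool = False

    @property
    def signal(self) -> bool:
        """True when all four algorithms flag the pair."""
        return self.ror_pos and self.prr_pos and self.bcpnn_pos and self.mgps_pos


def compute_signal(
    drug: str,
    t: ContingencyTable,
    *,
    ic_dispersion: str = "closed_form",
    continuity_correction: bool = False,
) -> SignalResult:
    """Compute all four statistics for one table (flags not yet set)."""
    ror = compute_ror(t, continuity_correction=continuity_correction)
    prr = compute_prr(t, continuity_correction=continuity_correction)
    ic = compute_ic(t, ic_dispersion=ic_dispersion)
    ebgm = compute_ebgm(t)
    return SignalResult(
        drug=drug, a=t.a, table=t,
        ror=ror.ror, ror_ci=(ror.ci_lower, ror.ci_upper),
        prr=prr.prr, prr_ci=(prr.ci_lower, prr.ci_upper), chi2=prr.chi2,
        ic=ic.ic, ic025=ic.ic025, ebgm=ebgm.ebgm, ebgm05=ebgm.ebgm05,
    )


def _gt(x: float, threshold: float) -> bool:
    return not math.isnan(x) and x > threshold


def evaluate_signal(r: SignalResult, crit: SignalCriteria = SignalCriteria()) -> SignalResult:
    """Apply the four positivity criteria; NaN statistics fail their flag."""
    r.ror_pos = r.a >= crit.min_a and _gt(r.ror_ci[0], crit.ror_lower_gt)
    r.prr_pos = (
        r.a >= crit.min_a
        and _gt(r.prr_ci[0], crit.prr_lower_gt)
        and not math.isnan(r.prr)
        and r.prr >= crit.prr_min
    )
    r.bcpnn_pos = _gt(r.ic025, crit.ic_lower_gt)
    r.mgps_pos = _gt(r.ebgm05, crit.ebgm05_gt)
    return r


def _rank_key(r: SignalResult) -> tuple[int, float, str]:
    # a desc, ror desc (NaN last), drugname asc
    ror = r.ror if not math.isnan(r.ror) else float("-inf")
    return (-r.a, -ror, r.drug)


def screen_marginals(
    marginals: MarginalCounts,
    crit: SignalCriteria = SignalCriteria(),
    *,
    min_count: int = 1,
    ic_dispersion: str = "closed_form",
    continuity_correction: bool = False,
) -> list[SignalResult]:
    """Screen every drug in a set of marginal counts against the event.

    One :class:`SignalResult` per drug with ``a >= min_count`` (default
    1), evaluated against ``crit`` and ranked by (a desc, ROR desc,
    name asc).
    """
    results = []
    for name, m in marginals.per_drug.items():
        if m.n_drug_event < max(min_count, 1):
            continue
        t = ContingencyTable.from_marginals(
            marginals.n_total, marginals.n_event, m.n_drug, m.n_drug_event
        )
        r = compute_signal(
            name, t, ic_dispersion=ic_dispersion,
            continuity_correction=continuity_correction,
        )
        results.append(evaluate_signal(r, crit))
    results.sort(key=_rank_key)
    return results


def screen_event(
    reports: Sequence[Report],
    event: EventDefinition,
    crit: SignalCriteria = SignalCriteria(),
    *,
    min_count: int = 1,
    ic_dispersion: str = "closed_form",
    continuity_correction: bool = False,
) -> list[SignalResult]:
    """Full screen: count marginals over deduplicated reports, then rank.

    Returns an empty list (with a warning) when the event never occurs.
    """
    marginals = count_marginals(reports, event)
    if marginals.n_event == 0:
        import logging

        logging.getLogger(__name__).warning(
            "screen_event: no report matches the event definition"
        )
        return []
    return screen_marginals(
        marginals, crit, min_count=min_count,
        ic_dispersion=ic_dispersion, continuity_correction=continuity_correction,
    )
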