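# Methods

This note records the statistical conventions, defaults and design choices
behind `pvsignal`, in the spirit of a model-description document: what is
computed, under which assumptions, and what the synthetic-data checks do and
do not establish about real spontaneous-report data.

## Data model and deduplication

A *report version* is one row of the DEMO table, identified by PRIMARYID; a
*case* is the set of versions sharing a CASEID. All analyses run on one
version per case: within each CASEID group the version with the maximal
`(fda_dt, primaryid)` pair is retained. The two published phrasings of the
tie rule (latest receipt date; highest PRIMARYID among date ties) are both
special cases of this single lexicographic maximum, which is what the
implementation uses. Versions with a missing receipt date sort earliest, so
they are only retained when no dated version exists; a warning is logged.
Deduplication operates on bare key triples before any table join, and every
decision is exportable as a delimited audit log.

Parsing is deliberately rigid: fields split on a literal `$` with no quoting
dialect, and a data line whose field count disagrees with the header is
quarantined with its line number rather than repaired or dropped. This makes
ingestion deterministic and attrition auditable. Readers accept any superset
of each table's required columns, since real quarters have accreted columns
over the years.

Dates are kept as YYYYMMDD integers with an explicit precision flag
(day / month / year / missing / invalid). Partial dates survive for
year-level summaries but are excluded — with a recorded reason — from any
day-resolution arithmetic.

## Counting conventions

The unit of counting is the report, not the drug–reaction line. A report
contributes at most once per distinct primary-suspect (PS) drug name, and
only PS entries count; secondary-suspect, concomitant and interacting roles
are excluded throughout. The denominator universe N is *all* deduplicated
reports in the study window, event and non-event alike — the d cell of the
2×2 table ("other drugs, other events") requires the full universe, and
non-event reports contribute to a drug's b cell under the same role filter.

Event matching is exact string equality after case-folding against a
configurable list of MedDRA preferred terms. No dictionary hierarchy or
standardized-query expansion is attempted; the event definition is data, not
code. Drug names are normalized by upper-casing, trimming and collapsing
internal whitespace only — no brand/generic or salt harmonization, which
belongs in user configuration if wanted.

## Disproportionality statistics

Four measures are computed per drug on the a/b/c/d table (formulas in the
README). Numerical conventions:

- **Zero cells.** No continuity correction by default: estimates whose
  closed form divides by zero are returned as NaN with a `defined=False`
  flag and fail their signal criterion. A Haldane–Anscombe +0.5 correction
  is available as an explicit opt-in.
- **χ²** is the uncorrected Pearson statistic (no Yates continuity
  correction), cross-checked in the tests against
  `scipy.stats.chi2_contingency(correction=False)`.
- **EBGM as implemented is the unshrunk observed-to-expected ratio**
  a·N/((a+c)(a+b)), so IC = log₂(EBGM) holds exactly — an identity the test
  suite asserts to machine precision, and which published screening tables
  of this form satisfy row by row. A true gamma-Poisson shrinkage estimator
  (prior fitting over the whole drug–event matrix) is a non-goal; the lower
  bound EBGM05 uses the same log-normal standard error as the ROR, as the
  printed interval form implies.
- **IC dispersion.** The default lower bound is IC025 = IC − 2·SD with
  SD(IC) = 1/(ln2·√(a+1)). This closed form is an inference: reference
  screening tables print (a, EBGM, IC, IC025) but no variance formula, and
  this form reproduces every printed IC025 across a = 4…56 to one unit in
  the last printed digit, while the √a variant fails (e.g. at a = 20).
  It is the large-margin limit of the BCPNN posterior variance, in which
  the a-cell term 1/(a+1) dominates. The full Bate-1998 Beta/Dirichlet
  posterior SD is available via `ic_dispersion="bate1998"`.
- **Ranking** of the screened table is (a desc, ROR desc, name asc);
  undefined RORs sort last within an a-group. Ties are therefore
  reproducible.
- **Multiple testing.** None is applied — conventional for this family of
  screens; the full-precision export carries all four per-algorithm flags so
  users can post-filter.

A monotonicity remark: with b, c, d held fixed, ROR and PRR strictly
increase in a, but IC and EBGM do not (N grows with a; e.g. the
observed/expected ratio at b=c=1, d=5 is 2, 2, 1.875 for a = 1, 2, 3). The
property that does hold for all four — and that the tests assert — is strict
increase under the margin-preserving shift (a+1, b−1, c−1, d+1).

## Time-to-onset

Latency is event onset date (DEMO `event_dt`) minus the *earliest
full-precision* therapy start among the report's PS entries for the drug —
the earliest start being the conservative exposure origin when a report
carries several entries for the same drug. Negative differences, partial
dates and invalid calendar values are excluded with per-record reasons.
Day-0 latencies are kept (the first bin includes 0).

Quantiles use linear interpolation between order statistics at position
h = (n−1)·p — the convention under which published per-drug medians take
fractional values such as 155.50 or 501.75 days, which nearest-rank
quantiles cannot produce. The histogram uses fixed 30-day bins 0–30,
31–60, …, 331–360 with an open >360 bin (day 30 falls in the first bin,
day 31 in the second, day 361 in the top bin). The cumulative onset curve is
the plain ECDF over sorted latencies; tests assert its consistency with the
bins (fraction at day 30 equals the first bin's share) and the quantiles
(ECDF at the median ≥ 0.5).

## Synthetic quarters and what they establish

The generator emulates the statistical skeleton of a FAERS quarter, not its
texture. Each report names exactly one PS drug, drawn from a configured
panel plus 20 background drugs; the probability that a report carries the
target event is min(1, p₀·λ_drug), so λ is a reporting-risk multiplier over
the baseline p₀. Defaults (chosen once, as study conditions): p₀ = 0.001 —
target-event rarity in the spirit of a real screen where ~1,500 event cases
sit in a database of tens of millions — 5% of cases republished as amended
versions, 30% of onset-relevant dates partial or missing, a decoy pool of 25
common reaction terms so b and d cells are well populated, and event onset
latencies log-normal with configurable per-drug median and shape σ = 1
(right-skewed, matching the heavy upper tails of real latency tables, where
Q3 can sit years beyond the median). Demographics, outcome codes and
reporter occupations are simple categorical draws (about half consumer
reporters). Determinism: one named RNG substream per concern, spawned from a
single seed, so a fixed seed yields byte-identical files; a truth-only fast
path (`generate_truth`) draws from the same substreams and provably matches
the full cohort, which keeps replicated calibration studies cheap.

Because λ multiplies a *probability* while the ROR estimates an *odds*
ratio, the two differ by the factor (1−p₀)/(1−λp₀) — at the default p₀ and
λ ≤ 20 this is under 2%, negligible against Monte-Carlo CI widths at the
sample sizes used. The calibration suite runs 200 replicates per λ ∈
{2, 5, 20} on cohorts of 50,000 reports (one spiked drug at PS probability
0.10 against 17 nulls) and checks that the ROR's 95% CI covers λ at the
nominal rate ±3 points, that a 20-fold spike fires all four criteria in
>99% of replicates, and that null drugs pass the joint gate in <1% of
drug-replicates.

What passing these checks does *not* show: robustness to drug-name spelling
variation, indication bias, polypharmacy confounding, duplicate reports that
evade the key rule (different CASEIDs for the same patient), or reporting
waves — none of which the generator emulates. Results on real data inherit
all the usual caveats of spontaneous-report disproportionality analysis:
statistical association, not causation, and no incidence estimation.

## Problem sizes in the shipped checks

Unit and property tests run on tables up to a few hundred counts and cohorts
of 8,000 reports; calibration uses 600 replicated 50,000-report cohorts via
the truth-only path (the report-level pipeline is first asserted equal to the
ground-truth counts on a full 50,000-report cohort); onset-median recovery
uses ~500 latency records at a configured 900-day median. These sizes were
chosen as the smallest at which the asserted tolerances are comfortably
identifiable.

## Known limitations

- Event matching is literal PT equality; standardized MedDRA queries or
  hierarchy expansion must be done upstream.
- EBGM is unshrunk (see above); small-count EBGM values are therefore more
  volatile than true MGPS output, which the a ≥ 3 and EBGM05 > 2 gates only
  partly offset.
- The XML FAERS distribution, INDI/RPSR tables, and record-linkage
  deduplication beyond the key rule are out of scope.
- The CLI is a thin convenience wrapper; the library API is the primary
  interface.
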