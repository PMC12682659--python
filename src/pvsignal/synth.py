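"""Synthetic FAERS-quarter generator with exact ground truth.

Real FAERS extracts cannot ship with a package, so every pipeline stage
is exercised against generated quarters whose report-level truth is
known exactly: which reports carry the target event, which drug is the
primary suspect, the true onset latency, and — when duplicate versions
are injected — which version the deduplication rule must retain.

The statistical model is deliberately simple.  Each report names
exactly one primary-suspect (PS) drug, drawn from a configured panel
plus a pool of background drugs; the probability that a report carries
the target event is ``min(1, baseline_event_prob · lambda_drug)``, so a
drug's ``lambda`` is the reporting-risk multiplier relative to the
background.  Event reports get an onset latency drawn from a log-normal
with a configurable median (heavy right tails, matching the strongly
right-skewed latencies seen in spontaneous reports).  Demographics,
outcomes and decoy reactions come from simple categorical draws.

Determinism: one named substream per concern, all spawned from the
configured seed, so a fixed seed yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cases import DrugMarginal, MarginalCounts
from .io import Report, ReportKey, write_ascii_table, normalize_drug_name

#: Default target preferred term (the queried adverse event).
DEFAULT_TARGET_PT = "Drug-induced polycystic ovary syndrome"

#: Decoy preferred-term pool: common FAERS reactions, so the b and d
#: cells of every contingency table are well populated.
DECOY_PTS: tuple[str, ...] = (
    "Headache", "Nausea", "Fatigue", "Dizziness", "Diarrhoea", "Rash",
    "Vomiting", "Pruritus", "Insomnia", "Arthralgia", "Dyspnoea", "Pyrexia",
    "Anxiety", "Weight increased", "Abdominal pain", "Cough", "Alopecia",
    "Myalgia", "Constipation", "Somnolence", "Tremor", "Palpitations",
    "Hyperhidrosis", "Dry mouth", "Oedema peripheral",
)

_SUBSTREAMS = (
    "drugs", "events", "onsets", "dates", "demographics",
    "reactions", "outcomes", "concomitant", "duplicates",
)


@dataclass(frozen=True)
class DrugSpec:
    """One configured drug: PS marginal probability, risk multiplier, latency median."""

    name: str
    marginal_prob: float
    lam: float = 1.0
    onset_median_days: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.marginal_prob <= 1.0:
            raise ValueError(f"marginal_prob out of [0,1] for {self.name!r}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be > 0 for {self.name!r}")


def default_drug_panel() -> tuple[DrugSpec, ...]:
    """A small null panel used when no drugs are configured."""
    return tuple(
        DrugSpec(f"DRUG {chr(65 + i)}", 0.02, 1.0) for i in range(5)
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic quarter.

    Defaults emulate spontaneous-report rarity: the target event is
    rare (``baseline_event_prob = 0.001``), most reports name a
    background drug, a few percent of cases are re-published as
    amended versions, and a sizeable fraction of dates are partial or
    missing (in FAERS only a minority of event reports document onset).
    """

    n_reports: int = 50_000
    drugs: tuple[DrugSpec, ...] = field(default_factory=default_drug_panel)
    baseline_event_prob: float = 0.001
    duplicate_rate: float = 0.05
    missing_date_rate: float = 0.30
    seed: int = 0
    target_pt: str = DEFAULT_TARGET_PT
    n_background_drugs: int = 20
    onset_sigma: float = 1.0
    default_onset_median: float = 180.0
    quarter_start: str = "2023-01-01"
    quarter_days: int = 90

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_event_prob <= 1.0:
            raise ValueError("baseline_event_prob out of [0,1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate out of [0,1)")
        if not 0.0 <= self.missing_date_rate <= 1.0:
            raise ValueError("missing_date_rate out of [0,1]")
        total = sum(d.marginal_prob for d in self.drugs)
        if total > 1.0 + 1e-12:
            raise ValueError(f"drug marginal probabilities sum to {total:.3f} > 1")


@dataclass
class GroundTruth:
    """Per-report labels and per-drug realized counts for one cohort.

    ``marginals`` are the counts the pipeline must reproduce after
    deduplication; ``lineage`` maps each duplicated caseid to its
    version primaryids and ``survivors`` to the version the key rule
    retains.
    """

    event: np.ndarray
    ps_drug: np.ndarray
    onset_days: np.ndarray
    marginals: MarginalCounts
    lineage: dict[int, tuple[int, ...]]
    survivors: dict[int, int]


def _dates_to_int(dates: np.ndarray) -> np.ndarray:
    """datetime64[D] -> YYYYMMDD int array."""
    y = dates.astype("datetime64[Y]").astype(int) + 1970
    m = dates.astype("datetime64[M]").astype(int) % 12 + 1
    d = (dates - dates.astype("datetime64[M]")).astype(int) + 1
    return y * 10000 + m * 100 + d


class Cohort:
    """One generated quarter held in memory as the five FAERS tables."""

    def __init__(
        self,
        config: SynthConfig,
        demo: pd.DataFrame,
        drug: pd.DataFrame,
        reac: pd.DataFrame,
        ther: pd.DataFrame,
        outc: pd.DataFrame,
        truth: GroundTruth,
    ) -> None:
        self.config = config
        self.demo = demo
        self.drug = drug
        self.reac = reac
        self.ther = ther
        self.outc = outc
        self.truth = truth

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "DEMO": self.demo, "DRUG": self.drug, "REAC": self.reac,
            "THER": self.ther, "OUTC": self.outc,
        }

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the five ``$``-delimited files plus the ground-truth export."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for kind, df in self.tables.items():
            path = directory / f"{kind}.txt"
            write_ascii_table(path, list(df.columns), df.itertuples(index=False))
            paths[kind] = path
        truth_path = directory / "GROUND_TRUTH.txt"
        write_ascii_table(
            truth_path,
            ("report_index", "event", "ps_drug", "onset_days"),
            (
                (i, int(e), d, "" if np.isnan(o) else int(o))
                for i, (e, d, o) in enumerate(
                    zip(self.truth.event, self.truth.ps_drug, self.truth.onset_days)
                )
            ),
        )
        paths["GROUND_TRUTH"] = truth_path
        return paths

    def to_reports(self) -> list[Report]:
        """Assemble the in-memory tables through the regular join path."""
        from .io import assemble_reports

        reports, _ = assemble_reports(
            self.demo.to_dict("records"),
            self.drug.to_dict("records"),
            self.reac.to_dict("records"),
            self.ther.to_dict("records"),
            self.outc.to_dict("records"),
            tolerate_duplicate_primaryid=False,
        )
        return reports


def _realized_marginals(event: np.ndarray, ps_drug: np.ndarray) -> MarginalCounts:
    counts = MarginalCounts(n_total=len(event), n_event=int(event.sum()))
    names, inverse = np.unique(ps_drug, return_inverse=True)
    n_drug = np.bincount(inverse, minlength=len(names))
    n_drug_event = np.bincount(inverse, weights=event.astype(float), minlength=len(names))
    for name, nd, nde in zip(names, n_drug, n_drug_event):
        counts.per_drug[str(name)] = DrugMarginal(int(nd), int(nde))
    counts.validate()
    return counts


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    return {name: np.random.default_rng(child)
            for name, child in zip(_SUBSTREAMS, root.spawn(len(_SUBSTREAMS)))}


def _draw_core(cfg: SynthConfig, rngs: dict[str, np.random.Generator]):
    """Drug assignment, event labels and onset latencies (shared substreams)."""
    n = cfg.n_reports
    panel = [replace(d, name=normalize_drug_name(d.name)) for d in cfg.drugs]
    bg_names = [f"BACKGROUND DRUG {i:02d}" for i in range(1, cfg.n_background_drugs + 1)]
    names = [d.name for d in panel] + bg_names
    probs = [d.marginal_prob for d in panel]
    remainder = 1.0 - sum(probs)
    probs += [remainder / len(bg_names)] * len(bg_names)
    lam = np.array([d.lam for d in panel] + [1.0] * len(bg_names))
    medians = np.array(
        [d.onset_median_days or cfg.default_onset_median for d in panel]
        + [cfg.default_onset_median] * len(bg_names)
    )
    drug_idx = rngs["drugs"].choice(len(names), size=n, p=np.asarray(probs))
    ps_drug = np.asarray(names, dtype=object)[drug_idx]

    p_event = np.minimum(1.0, cfg.baseline_event_prob * lam[drug_idx])
    event = rngs["events"].random(n) < p_event
    onset = np.full(n, np.nan)
    n_event = int(event.sum())
    if n_event:
        mu = np.log(medians[drug_idx[event]])
        onset[event] = np.rint(
            rngs["onsets"].lognormal(mean=0.0, sigma=cfg.onset_sigma, size=n_event)
            * np.exp(mu)
        )
    return names, bg_names, drug_idx, ps_drug, event, onset


def generate_truth(cfg: SynthConfig) -> GroundTruth:
    """Ground truth only, without materializing the five tables.

    Draws from the same named substreams as :func:`generate_cohort`, so
    for a given config the labels and realized marginal counts are
    identical to the full cohort's — useful for replicated calibration
    studies where building the ASCII tables would dominate runtime.
    Duplicate lineage is left empty (no versions are materialized).
    """
    rngs = _spawn_rngs(cfg.seed)
    _, _, _, ps_drug, event, onset = _draw_core(cfg, rngs)
    return GroundTruth(
        event=event, ps_drug=ps_drug, onset_days=onset,
        marginals=_realized_marginals(event, ps_drug),
        lineage={}, survivors={},
    )


def generate_cohort(cfg: SynthConfig) -> Cohort:
    """Generate one synthetic quarter with exact ground truth.

    Deterministic for a fixed ``cfg.seed``; every stochastic concern
    draws from its own named substream so that changing, say, the
    duplicate rate does not perturb the event assignment.
    """
    n = cfg.n_reports
    rngs = _spawn_rngs(cfg.seed)
    names, bg_names, drug_idx, ps_drug, event, onset = _draw_core(cfg, rngs)

    # --- dates ---------------------------------------------------------------
    rd = rngs["dates"]
    q0 = np.datetime64(cfg.quarter_start, "D")
    fda = q0 + rd.integers(0, cfg.quarter_days, size=n)
    event_date = fda - rd.integers(0, 120, size=n)
    start_date = np.where(
        event,
        event_date - np.nan_to_num(onset, nan=0.0).astype(int),
        event_date - rd.integers(1, 365, size=n),
    ).astype("datetime64[D]")
    fda_int = _dates_to_int(fda)
    event_int = _dates_to_int(event_date).astype(object)
    start_int = _dates_to_int(start_date).astype(object)
    # degrade a fraction of event/start dates to month precision or missing
    for col, rate in ((event_int, cfg.missing_date_rate), (start_int, cfg.missing_date_rate)):
        u = rd.random(n)
        col[u < rate / 2] = None  # missing
        partial = (u >= rate / 2) & (u < rate)
        col[partial] = [v // 100 for v in col[partial]]  # YYYYMM

    # --- demographics --------------------------------------------------------
    rg = rngs["demographics"]
    age = np.clip(rg.normal(32, 12, size=n), 12, 85).round(0)
    age_missing = rg.random(n) < 0.08
    sex = rg.choice(np.array(["F", "M", ""], dtype=object), size=n, p=[0.62, 0.33, 0.05])
    wt_kg = np.clip(rg.normal(70, 15, size=n), 35, 160).round(1)
    wt_missing = rg.random(n) < 0.20
    in_lbs = rg.random(n) < 0.10
    countries = np.array(["US", "CA", "GB", "JP", "FR", "DE", "AU", "IT"], dtype=object)
    country = rg.choice(countries, size=n, p=[0.55, 0.10, 0.08, 0.07, 0.06, 0.06, 0.04, 0.04])
    occp = rg.choice(
        np.array(["CN", "MD", "OT", "PH", "LW", ""], dtype=object),
        size=n, p=[0.505, 0.207, 0.102, 0.08, 0.01, 0.096],
    )

    # --- duplicate versions ---------------------------------------------------
    base_pid = 100_000_001 + 10 * np.arange(n, dtype=np.int64)
    caseid = 40_000_001 + np.arange(n, dtype=np.int64)
    rdup = rngs["duplicates"]
    n_dup_cases = int(round(cfg.duplicate_rate * n))
    dup_case_idx = np.sort(rdup.choice(n, size=n_dup_cases, replace=False)) \
        if n_dup_cases else np.empty(0, dtype=int)
    extra_counts = rdup.integers(1, 4, size=n_dup_cases) if n_dup_cases else np.empty(0, dtype=int)
    dup_base = np.repeat(dup_case_idx, extra_counts)
    version_rank = np.concatenate([np.arange(1, k + 1) for k in extra_counts]) \
        if n_dup_cases else np.empty(0, dtype=int)
    dup_pid = base_pid[dup_base] + version_rank
    # offsets >= 0; zero offsets create fda_dt ties resolved by primaryid
    dup_offset = rdup.integers(0, 45, size=len(dup_base))
    dup_offset[rdup.random(len(dup_base)) < 0.3] = 0
    dup_fda_int = _dates_to_int((fda[dup_base] + dup_offset))

    version_base = np.concatenate([np.arange(n), dup_base]).astype(int)
    version_pid = np.concatenate([base_pid, dup_pid])
    version_fda = np.concatenate([fda_int, dup_fda_int])

    lineage: dict[int, tuple[int, ...]] = {}
    survivors: dict[int, int] = {}
    if n_dup_cases:
        groups: dict[int, list[tuple[int, int]]] = {}
        for b, pid, fdt in zip(dup_base, dup_pid, dup_fda_int):
            groups.setdefault(int(b), []).append((int(fdt), int(pid)))
        for b, extras in groups.items():
            cid = int(caseid[b])
            versions = [(int(fda_int[b]), int(base_pid[b]))] + extras
            lineage[cid] = tuple(pid for _, pid in versions)
            survivors[cid] = max(versions)[1]

    # --- DEMO -----------------------------------------------------------------
    vb = version_base
    demo = pd.DataFrame({
        "primaryid": version_pid,
        "caseid": caseid[vb],
        "fda_dt": version_fda,
        "event_dt": event_int[vb],
        "age": np.where(age_missing[vb], None, age[vb].astype(object)),
        "age_cod": np.where(age_missing[vb], None, "YR"),
        "sex": sex[vb],
        "wt": np.where(
            wt_missing[vb], None,
            np.where(in_lbs[vb], (wt_kg[vb] * 2.20462).round(1), wt_kg[vb]).astype(object),
        ),
        "wt_cod": np.where(wt_missing[vb], None, np.where(in_lbs[vb], "LBS", "KG")),
        "reporter_country": country[vb],
        "occp_cod": occp[vb],
    })

    # --- DRUG / THER ----------------------------------------------------------
    rc = rngs["concomitant"]
    n_extra = rc.choice([0, 1, 2], size=n, p=[0.5, 0.3, 0.2])
    extra_role = rc.choice(np.array(["C", "SS", "I"], dtype=object), size=int(n_extra.sum()),
                           p=[0.7, 0.2, 0.1])
    extra_drug = rc.choice(np.asarray(bg_names, dtype=object), size=int(n_extra.sum()))

    base_drug_rows = pd.DataFrame({
        "base": np.arange(n), "drug_seq": 1, "drugname": ps_drug, "role_cod": "PS",
    })
    extra_base = np.repeat(np.arange(n), n_extra)
    extra_seq = np.concatenate([np.arange(2, k + 2) for k in n_extra]) \
        if len(extra_base) else np.empty(0, dtype=int)
    extra_rows = pd.DataFrame({
        "base": extra_base, "drug_seq": extra_seq,
        "drugname": extra_drug, "role_cod": extra_role,
    })
    drug_base = pd.concat([base_drug_rows, extra_rows], ignore_index=True)
    drug_base.sort_values(["base", "drug_seq"], kind="stable", inplace=True)

    version_map = pd.DataFrame({"base": version_base, "primaryid": version_pid,
                                "caseid": caseid[version_base]})
    drug_df = version_map.merge(drug_base, on="base", how="inner")
    drug_df = drug_df[["primaryid", "caseid", "drug_seq", "drugname", "role_cod"]]
    drug_df.sort_values(["primaryid", "drug_seq"], kind="stable", inplace=True)

    ther_base = pd.DataFrame({
        "base": np.arange(n), "dsg_drug_seq": 1, "start_dt": start_int, "end_dt": None,
    })
    ther_df = version_map.merge(ther_base, on="base", how="inner")
    ther_df = ther_df[ther_df["start_dt"].notna()]
    ther_df = ther_df[["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"]]
    ther_df.sort_values(["primaryid"], kind="stable", inplace=True)

    # --- REAC -----------------------------------------------------------------
    rr = rngs["reactions"]
    n_decoy = rr.poisson(1.0, size=n) + (~event).astype(int)  # events may have 0 decoys
    decoy_base = np.repeat(np.arange(n), n_decoy)
    decoy_pt = rr.choice(np.asarray(DECOY_PTS, dtype=object), size=len(decoy_base))
    reac_base = pd.concat([
        pd.DataFrame({"base": np.flatnonzero(event), "pt": cfg.target_pt}),
        pd.DataFrame({"base": decoy_base, "pt": decoy_pt}),
    ], ignore_index=True)
    reac_base.sort_values(["base"], kind="stable", inplace=True)
    reac_df = version_map.merge(reac_base, on="base", how="inner")
    reac_df = reac_df[["primaryid", "caseid", "pt"]]
    reac_df.sort_values(["primaryid"], kind="stable", inplace=True)

    # --- OUTC -----------------------------------------------------------------
    ro = rngs["outcomes"]
    n_outc = ro.choice([0, 1, 2], size=n, p=[0.2, 0.6, 0.2])
    outc_base_idx = np.repeat(np.arange(n), n_outc)
    outc_codes = ro.choice(
        np.array(["OT", "HO", "DS", "RI", "DE", "LT", "CA"], dtype=object),
        size=len(outc_base_idx), p=[0.469, 0.278, 0.07, 0.08, 0.05, 0.04, 0.013],
    )
    outc_base = pd.DataFrame({"base": outc_base_idx, "outc_cod": outc_codes})
    outc_base = outc_base.drop_duplicates()  # at most one row per (report, code)
    outc_df = version_map.merge(outc_base, on="base", how="inner")
    outc_df = outc_df[["primaryid", "caseid", "outc_cod"]]
    outc_df.sort_values(["primaryid"], kind="stable", inplace=True)

    truth = GroundTruth(
        event=event,
        ps_drug=ps_drug,
        onset_days=onset,
        marginals=_realized_marginals(event, ps_drug),
        lineage=lineage,
        survivors=survivors,
    )
    demo.sort_values("primaryid", kind="stable", inplace=True)
    return Cohort(cfg, demo.reset_index(drop=True), drug_df.reset_index(drop=True),
                  reac_df.reset_index(drop=True), ther_df.reset_index(drop=True),
                  outc_df.reset_index(drop=True), truth)


def generate_quarter(cfg: SynthConfig, out_dir: str | Path) -> tuple[dict[str, Path], GroundTruth]:
    """Generate a quarter and write its five ASCII files (plus ground truth)."""
    cohort = generate_cohort(cfg)
    return cohort.write(out_dir), cohort.truth


def inject_duplicates(
    reports: Sequence[Report], rate: float, seed: int
) -> tuple[list[Report], dict[int, int]]:
    """Emit report versions: some cases gain 1–3 amended copies.

    Injected versions share the parent's caseid and content but carry a
    distinct, higher primaryid and a later-or-equal fda_dt.  Returns
    the expanded version list plus the intended survivor per duplicated
    caseid (the lexicographic maximum on ``(fda_dt, primaryid)``).
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = list(reports)
    survivors: dict[int, int] = {}
    if not reports:
        return out, survivors
    max_pid = max(r.key.primaryid for r in reports)
    next_pid = max_pid + 1
    n_pick = int(round(rate * len(reports)))
    picked = rng.choice(len(reports), size=n_pick, replace=False) if n_pick else []
    for idx in sorted(int(i) for i in picked):
        parent = reports[idx]
        versions = [(parent.key.fda_dt or -1, parent.key.primaryid)]
        for _ in range(int(rng.integers(1, 4))):
            offset = int(rng.integers(0, 45)) if rng.random() >= 0.3 else 0
            base = parent.key.fda_dt
            if base is not None:
                d = pd.Timestamp(str(base)) + pd.Timedelta(days=offset)
                new_fda = int(d.strftime("%Y%m%d"))
            else:
                new_fda = None
            key = ReportKey(primaryid=next_pid, caseid=parent.key.caseid, fda_dt=new_fda)
            next_pid += 1
            out.append(replace(parent, key=key))
            versions.append((new_fda if new_fda is not None else -1, key.primaryid))
        survivors[parent.key.caseid] = max(versions)[1]
    return out, survivors
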