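"""Shared fixtures: small synthetic quarters and report builders."""

from __future__ import annotations

import pytest

from pvsignal import (
    DrugEntry,
    DrugSpec,
    FaersDate,
    Report,
    ReportKey,
    SynthConfig,
    generate_cohort,
)


def make_report(
    primaryid: int,
    *,
    caseid: int | None = None,
    fda_dt: int | None = 20200315,
    reactions: tuple[str, ...] = (),
    drugs: tuple[tuple[str, str], ...] = (),
    event_dt: int | None = None,
    **demo,
) -> Report:
    """Terse report builder: drugs given as (name, role) pairs."""
    return Report(
        key=ReportKey(primaryid, caseid if caseid is not None else primaryid, fda_dt),
        event_dt=FaersDate.parse(event_dt),
        drugs=tuple(DrugEntry(drugname=n, role=r) for n, r in drugs),
        reactions=reactions,
        **demo,
    )


@pytest.fixture(scope="session")
def spiked_config() -> SynthConfig:
    """A moderate cohort with one strongly associated drug and nulls."""
    return SynthConfig(
        n_reports=8000,
        seed=20240915,
        baseline_event_prob=0.005,
        duplicate_rate=0.10,
        drugs=(
            DrugSpec("Olanzapine", 0.04, lam=15.0, onset_median_days=150.0),
            DrugSpec("Valproic acid", 0.02, lam=8.0, onset_median_days=900.0),
            DrugSpec("Null drug", 0.03, lam=1.0),
        ),
    )


@pytest.fixture(scope="session")
def spiked_cohort(spiked_config):
    return generate_cohort(spiked_config)


@pytest.fixture(scope="session")
def spiked_quarter_dir(tmp_path_factory, spiked_cohort):
    """The spiked cohort written out as a quarter directory."""
    d = tmp_path_factory.mktemp("quarter")
    spiked_cohort.write(d)
    return d
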