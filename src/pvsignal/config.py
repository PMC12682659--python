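"""Structured analysis configuration (YAML-backed).

Collects the knobs the pipeline exposes — target preferred terms,
signal criteria thresholds, IC dispersion choice, continuity
correction, minimum count — so a whole screen is reproducible from one
file plus the input quarter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cases import EventDefinition
from .stats import SignalCriteria
from .synth import DEFAULT_TARGET_PT


@dataclass
class AnalysisConfig:
    pt_terms: tuple[str, ...] = (DEFAULT_TARGET_PT,)
    min_a: int = 3
    prr_min: float = 2.0
    ebgm05_gt: float = 2.0
    ic_lower_gt: float = 0.0
    min_count: int = 1
    ic_dispersion: str = "closed_form"
    continuity_correction: bool = False

    def event(self) -> EventDefinition:
        return EventDefinition(tuple(self.pt_terms))

    def criteria(self) -> SignalCriteria:
        return SignalCriteria(
            min_a=self.min_a, prr_min=self.prr_min,
            ebgm05_gt=self.ebgm05_gt, ic_lower_gt=self.ic_lower_gt,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pt_terms"] = list(self.pt_terms)
        return d

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "pt_terms" in data:
            data["pt_terms"] = tuple(data["pt_terms"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
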