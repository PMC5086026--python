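"""Pipeline configuration.

Every tunable constant of the weighting algorithm lives here with its
published default: the medication-weight bands, the 6-SD outlier rule, the
minimally-active screen, the k-means settings, the phenotype collapse map,
the secure-message escalation thresholds, the inactive-cluster weight, and
the train/test split fraction.  Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

DATE_FMT = "%Y-%m-%d"


def _parse_date(value: str | dt.date) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.datetime.strptime(value, DATE_FMT).date()


@dataclass
class Window:
    """Half-open observation window [start, end)."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        self.start = _parse_date(self.start)
        self.end = _parse_date(self.end)
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} must be after start {self.start}")

    @property
    def days(self) -> int:
        return (self.end - self.start).days

    def to_dict(self) -> dict:
        return {"start": self.start.isoformat(), "end": self.end.isoformat()}


@dataclass
class MedWeightBands:
    """Per-visit weight as a step function of the active-medication count."""

    low_max: int = 5        # <= low_max medications -> low weight
    mid_max: int = 10       # low_max < count <= mid_max -> mid weight
    low: float = 1.0
    mid: float = 1.5
    high: float = 1.75


@dataclass
class RuleThresholds:
    """Decision-rule screens applied before clustering."""

    outlier_sd: float = 6.0            # raw PCP visits > mean + outlier_sd * sd
    max_pcp: float = 1.0               # minimally-active screen follows
    max_ed: float = 0.0
    max_hospitalizations: float = 0.0  # emergent + elective combined
    max_specialty: float = 4.0
    max_telephone: float = 2.0
    max_msgs_to_patient: float = 6.0


@dataclass
class KMeansSettings:
    k: int = 4
    split_k: int = 2
    restarts: int = 5
    max_iter: int = 10


@dataclass
class EscalationThresholds:
    msg_sd: float = 1.5          # messages sent, relative to group mean
    max_msgs_to_patient: int = 24  # messages received from the care team


DEFAULT_COLLAPSE_MAP = {
    "A": "X", "B": "X",
    "C": "Y", "D": "Y",
    "E": "Z", "F": "Z", "G": "Z",
}


@dataclass
class PipelineConfig:
    year1: Window = field(default_factory=lambda: Window("2013-02-01", "2014-02-01"))
    year2: Window = field(default_factory=lambda: Window("2014-02-01", "2015-02-01"))
    med_weights: MedWeightBands = field(default_factory=MedWeightBands)
    rules: RuleThresholds = field(default_factory=RuleThresholds)
    kmeans: KMeansSettings = field(default_factory=KMeansSettings)
    escalation: EscalationThresholds = field(default_factory=EscalationThresholds)
    collapse_map: dict = field(default_factory=lambda: dict(DEFAULT_COLLAPSE_MAP))
    inactive_weight: float = 0.05
    train_fraction: float = 0.7
    payer_scheme: str = "three_level"  # or "four_level"
    min_panel: int = 150
    log_offset: float = 1.0            # outcome modelled as log(y + log_offset)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["year1"] = self.year1.to_dict()
        d["year2"] = self.year2.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        for key, sub in [
            ("year1", Window), ("year2", Window), ("med_weights", MedWeightBands),
            ("rules", RuleThresholds), ("kmeans", KMeansSettings),
            ("escalation", EscalationThresholds),
        ]:
            if key in d:
                val = d.pop(key)
                kwargs[key] = val if isinstance(val, sub) else sub(**val)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable short hash of the full configuration, for output provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
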