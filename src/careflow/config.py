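"""Run configuration: study calendar, replication count, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Study calendar and experiment settings.

    The default calendar covers a two-year parameterisation period
    (study start to the end of the lockdown year) and a three-year
    simulated recovery period, with weekly output bins anchored at
    ``study_start``.  The pre-lockdown year is treated as warm-up.
    """

    study_start: date = date(2019, 4, 1)
    lockdown_start: date = date(2020, 4, 1)
    post_lockdown_start: date = date(2021, 4, 1)
    horizon_end: date = date(2024, 4, 1)
    n_replications: int = 35
    base_seed: int = 1
    warm_start: bool = False

    def __post_init__(self) -> None:
        order = (
            self.study_start,
            self.lockdown_start,
            self.post_lockdown_start,
            self.horizon_end,
        )
        if any(a >= b for a, b in zip(order, order[1:])):
            raise ValueError("config dates must be strictly increasing")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")

    @property
    def horizon_days(self) -> int:
        return (self.horizon_end - self.study_start).days

    @property
    def warmup_weeks(self) -> int:
        return (self.lockdown_start - self.study_start).days // 7

    def week_of(self, when: date) -> int:
        return (when - self.study_start).days // 7

    def to_dict(self) -> dict:
        out = asdict(self)
        for key in ("study_start", "lockdown_start", "post_lockdown_start", "horizon_end"):
            out[key] = out[key].isoformat()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for key in ("study_start", "lockdown_start", "post_lockdown_start", "horizon_end"):
            if key in kwargs and not isinstance(kwargs[key], date):
                kwargs[key] = date.fromisoformat(str(kwargs[key]))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
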