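"""Length-of-stay (LOS) distributions.

Stays in mental-health services are right-skewed: many short contacts, a
long tail of extended episodes of care.  The default family is therefore
lognormal.  Durations are sampled in continuous days, multiplied by any
scenario scaling factor, and then discretised to whole days with a floor of
one day, matching the daily time step of the simulator.

Families
--------
``lognormal``   params ``mu``, ``sigma`` on the log-day scale
``exponential`` param ``mean`` (days)
``geometric``   param ``mean`` (days); memoryless in discrete time
``fixed``       param ``days``
``empirical``   param ``values``: list of day counts resampled uniformly
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

_FAMILIES = ("lognormal", "exponential", "geometric", "fixed", "empirical")

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class LosDistribution:
    """A duration sampler for one service, in days."""

    family: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown LOS family {self.family!r}; expected one of {_FAMILIES}")
        p = self.params
        if self.family == "lognormal":
            if "mu" not in p or "sigma" not in p:
                raise ValueError("lognormal LOS needs 'mu' and 'sigma'")
            if p["sigma"] < 0:
                raise ValueError("sigma must be >= 0")
        elif self.family in ("exponential", "geometric"):
            if p.get("mean", 0) <= 0:
                raise ValueError(f"{self.family} LOS needs positive 'mean'")
        elif self.family == "fixed":
            if p.get("days", 0) <= 0:
                raise ValueError("fixed LOS needs positive 'days'")
        elif self.family == "empirical":
            values = np.asarray(p.get("values", ()), dtype=float)
            if values.size == 0 or (values <= 0).any():
                raise ValueError("empirical LOS needs a non-empty list of positive day counts")

    # -- constructors -----------------------------------------------------

    @classmethod
    def lognormal_from_mean(cls, mean_days: float, sigma: float) -> "LosDistribution":
        """Lognormal with a given arithmetic mean (days) and log-sd ``sigma``."""
        if mean_days <= 0:
            raise ValueError("mean_days must be positive")
        mu = math.log(mean_days) - 0.5 * sigma**2
        return cls("lognormal", {"mu": mu, "sigma": sigma})

    @classmethod
    def lognormal_from_median(cls, median_days: float, sigma: float) -> "LosDistribution":
        if median_days <= 0:
            raise ValueError("median_days must be positive")
        return cls("lognormal", {"mu": math.log(median_days), "sigma": sigma})

    @classmethod
    def from_config(cls, config: dict[str, Any]) -> "LosDistribution":
        config = dict(config)
        family = config.pop("family")
        return cls(family, config)

    def to_config(self) -> dict[str, Any]:
        out: dict[str, Any] = {"family": self.family}
        for k, v in self.params.items():
            if isinstance(v, np.ndarray):
                v = [float(x) for x in v]
            out[k] = v
        return out

    # -- sampling ---------------------------------------------------------

    def sample_continuous(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Raw continuous draws in days (before scaling/discretisation)."""
        p = self.params
        if self.family == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], size)
        if self.family == "exponential":
            return rng.exponential(p["mean"], size)
        if self.family == "geometric":
            # geometric on {1, 2, ...} with mean p['mean']
            prob = min(1.0, 1.0 / float(p["mean"]))
            return rng.geometric(prob, size).astype(float)
        if self.family == "fixed":
            return np.full(size, float(p["days"]))
        values = np.asarray(p["values"], dtype=float)
        return values[rng.integers(0, values.size, size)]

    def sample_days(self, rng: np.random.Generator, size: int, scale: float = 1.0) -> np.ndarray:
        """Sample integer day counts (>= 1), with a multiplicative scale factor."""
        draws = self.sample_continuous(rng, size) * scale
        return np.maximum(1, np.rint(draws)).astype(np.int64)

    # -- moments ----------------------------------------------------------

    def mean_days(self) -> float:
        """Mean of the continuous distribution (before discretisation)."""
        p = self.params
        if self.family == "lognormal":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        if self.family in ("exponential", "geometric"):
            return float(p["mean"])
        if self.family == "fixed":
            return float(p["days"])
        return float(np.mean(p["values"]))

    def mean_weeks(self) -> float:
        return self.mean_days() / DAYS_PER_WEEK
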