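"""Simulation parameterisation: per-service rates, stays, transitions,
capacities and reneging behaviour.

A :class:`ModelParameters` object is the contract between the process-mining
side (which estimates these quantities from an event log) and the simulator
(which consumes them).  It serialises to a YAML schema::

    services:
      - id: L2_GP_high
        level: 2
        arrival_rate_per_day: 10.0
        capacity: 268            # omit or null for unlimited
        los: {family: lognormal, mu: ..., sigma: 0.8}
        transitions: {L3_IAPT_assessment: 0.2, L4_MHP_triage: 0.3, exit: 0.5}
        renege:
          threshold_days: 28
          hazard: 1.0
          destinations: {L4_MHP_triage: 0.5, exit: 0.5}

Windowed capacity/LOS/flow modifiers (set by intervention scenarios) are
carried on the same object; the simulator compiles them to per-day arrays.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import yaml

from .los import LosDistribution
from .services import EXIT, SERVICE_LEVELS, SERVICES, level_of

ROW_TOL = 1e-9


def _check_prob_map(mapping: dict[str, float], what: str) -> None:
    if any(v < 0 for v in mapping.values()):
        raise ValueError(f"{what}: negative probability in {mapping}")
    total = sum(mapping.values())
    if abs(total - 1.0) > ROW_TOL:
        raise ValueError(f"{what}: probabilities sum to {total!r}, expected 1")


@dataclass(frozen=True)
class WindowedFactor:
    """A multiplicative factor active on [start, end)."""

    start: date
    end: date
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    def active_on(self, day: date) -> bool:
        return self.start <= day < self.end


@dataclass(frozen=True)
class WindowedFlowFactor:
    """A multiplicative factor on one outgoing transition edge, on [start, end)."""

    target: str
    start: date
    end: date
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("factor must be positive")
        if self.start >= self.end:
            raise ValueError("window start must precede end")


@dataclass
class RenegeConfig:
    """Queue-abandonment behaviour for one service.

    A patient becomes eligible to renege once their wait exceeds
    ``threshold_days``; each subsequent day they renege with probability
    ``hazard`` (1.0 = deterministic renege the day the threshold is passed).
    On reneging, the destination -- an escalation service's queue or outright
    exit from the pathway -- is drawn from ``destinations``.
    """

    threshold_days: int
    hazard: float = 1.0
    destinations: dict[str, float] = field(default_factory=lambda: {EXIT: 1.0})

    def __post_init__(self) -> None:
        if self.threshold_days <= 0:
            raise ValueError("renege threshold must be positive")
        if not 0.0 < self.hazard <= 1.0:
            raise ValueError("renege hazard must be in (0, 1]")
        for dest in self.destinations:
            if dest != EXIT:
                level_of(dest)
        _check_prob_map(self.destinations, "renege destinations")


@dataclass
class ServiceParams:
    """All parameters for one capacity-constrained service node."""

    service_id: str
    level: int
    arrival_rate: float  # external arrivals per day
    los: LosDistribution
    transitions: dict[str, float]  # over services + EXIT
    capacity: float = math.inf  # max concurrent patients; inf = unlimited
    renege: RenegeConfig | None = None
    # windowed scenario modifiers (applied by the scenario engine)
    capacity_factors: list[WindowedFactor] = field(default_factory=list)
    los_factors: list[WindowedFactor] = field(default_factory=list)
    flow_factors: list[WindowedFlowFactor] = field(default_factory=list)

    def validate(self) -> None:
        if self.service_id in SERVICE_LEVELS and self.level != level_of(self.service_id):
            raise ValueError(
                f"{self.service_id}: level {self.level} inconsistent with service id"
            )
        if self.arrival_rate < 0:
            raise ValueError(f"{self.service_id}: arrival rate must be >= 0")
        if self.capacity < 0:
            raise ValueError(f"{self.service_id}: capacity must be >= 0")
        _check_prob_map(self.transitions, f"{self.service_id} transition row")

    # -- effective (windowed) values --------------------------------------

    def capacity_on(self, day: date) -> float:
        cap = self.capacity
        for wf in self.capacity_factors:
            if wf.active_on(day):
                cap *= wf.factor
        if math.isinf(cap):
            return cap
        # whole caseload slots, never below one
        return max(1, round(cap))

    def los_scale_on(self, day: date) -> float:
        scale = 1.0
        for wf in self.los_factors:
            if wf.active_on(day):
                scale *= wf.factor
        return scale

    def effective_los_mean_weeks(self, day: date) -> float:
        return self.los.mean_weeks() * self.los_scale_on(day)

    def transition_row_on(self, day: date) -> dict[str, float]:
        """Transition row with active flow factors applied.

        Scaled edges take their multiplied mass; untouched edges are rescaled
        proportionally so the row still sums to one.
        """
        active = [ff for ff in self.flow_factors if ff.start <= day < ff.end]
        if not active:
            return dict(self.transitions)
        return renormalise_row(self.transitions, {ff.target: ff.factor for ff in active})


def renormalise_row(row: dict[str, float], edge_factors: dict[str, float]) -> dict[str, float]:
    """Scale named edges of a probability row and renormalise the rest.

    The named edges are multiplied by their factors; the remaining entries
    are scaled by a common constant so the row sums to one.  Raises if the
    scaled edges alone exceed probability one.
    """
    touched: dict[str, float] = {}
    for target, factor in edge_factors.items():
        if target not in row:
            raise KeyError(f"flow factor targets absent edge {target!r}")
        touched[target] = row[target] * factor
    touched_mass = sum(touched.values())
    if touched_mass > 1.0 + ROW_TOL:
        raise ValueError(f"scaled edges carry probability {touched_mass:.4f} > 1")
    untouched = {k: v for k, v in row.items() if k not in touched}
    untouched_mass = sum(untouched.values())
    if untouched_mass <= 0:
        if abs(touched_mass - 1.0) > 1e-6:
            raise ValueError("no untouched mass left to renormalise against")
        return touched
    scale = (1.0 - touched_mass) / untouched_mass
    out = {k: v * scale for k, v in untouched.items()}
    out.update(touched)
    return {k: out[k] for k in row}  # preserve original key order


@dataclass
class ModelParameters:
    """The full parameter set for the ten-service system."""

    services: dict[str, ServiceParams]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = set(self.services)
        for sid, sp in self.services.items():
            if sid != sp.service_id:
                raise ValueError(f"key {sid!r} does not match service id {sp.service_id!r}")
            sp.validate()
            for dest in sp.transitions:
                if dest != EXIT and dest not in ids:
                    raise ValueError(f"{sid}: transition to unknown service {dest!r}")
            if sp.renege is not None:
                for dest in sp.renege.destinations:
                    if dest != EXIT and dest not in ids:
                        raise ValueError(f"{sid}: renege destination {dest!r} unknown")

    @property
    def service_ids(self) -> list[str]:
        return list(self.services)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def transition_matrix(self) -> np.ndarray:
        """Dense base transition matrix over services + exit (last column)."""
        ids = self.service_ids
        n = len(ids)
        mat = np.zeros((n, n + 1))
        index = {sid: j for j, sid in enumerate(ids)}
        for i, sid in enumerate(ids):
            for dest, p in self.services[sid].transitions.items():
                mat[i, n if dest == EXIT else index[dest]] = p
        return mat

    def effective_arrival_rates(self) -> dict[str, float]:
        """Long-run total arrival rate into each service (external + routed).

        Solves the open-network traffic equations lambda = lambda_ext + Q^T
        lambda for the base (unwindowed) transition structure.  Reneging
        flows are ignored, so this is the capacity-free throughput.
        """
        ids = self.service_ids
        n = len(ids)
        q = self.transition_matrix()[:, :n]
        ext = np.array([self.services[s].arrival_rate for s in ids])
        lam = np.linalg.solve(np.eye(n) - q.T, ext)
        return dict(zip(ids, lam))

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        out = []
        for sp in self.services.values():
            entry: dict = {
                "id": sp.service_id,
                "level": sp.level,
                "arrival_rate_per_day": float(sp.arrival_rate),
                "capacity": None if math.isinf(sp.capacity) else float(sp.capacity),
                "los": sp.los.to_config(),
                "transitions": {k: float(v) for k, v in sp.transitions.items()},
            }
            if sp.renege is not None:
                entry["renege"] = {
                    "threshold_days": sp.renege.threshold_days,
                    "hazard": sp.renege.hazard,
                    "destinations": {k: float(v) for k, v in sp.renege.destinations.items()},
                }
            out.append(entry)
        return {"services": out}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        services: dict[str, ServiceParams] = {}
        for entry in data["services"]:
            renege = None
            if entry.get("renege"):
                r = entry["renege"]
                renege = RenegeConfig(
                    threshold_days=int(r["threshold_days"]),
                    hazard=float(r.get("hazard", 1.0)),
                    destinations={k: float(v) for k, v in r["destinations"].items()},
                )
            cap = entry.get("capacity")
            services[entry["id"]] = ServiceParams(
                service_id=entry["id"],
                level=int(entry["level"]),
                arrival_rate=float(entry["arrival_rate_per_day"]),
                los=LosDistribution.from_config(entry["los"]),
                transitions={k: float(v) for k, v in entry["transitions"].items()},
                capacity=math.inf if cap is None else float(cap),
                renege=renege,
            )
        return cls(services)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Illustrative defaults
# ---------------------------------------------------------------------------

# External demand enters mainly through general practice, as in the mined
# pathway network; downstream services are fed by transitions.  Rates are
# scaled roughly an order of magnitude below the real system's volumes.
_DEFAULT_EXTERNAL_RATES = {
    "L2_GP_high": 10.0,
    "L2_GP_low": 6.0,
}

# Sparse transition structure: GP feeds IAPT and MHP triage; triage routes
# into the community MHP services; crisis and specialist feed inpatient care.
_DEFAULT_TRANSITIONS: dict[str, dict[str, float]] = {
    "L2_GP_high": {"L3_IAPT_assessment": 0.2, "L4_MHP_triage": 0.3, EXIT: 0.5},
    "L2_GP_low": {"L2_GP_high": 0.35, "L3_IAPT_assessment": 0.15, EXIT: 0.5},
    "L3_IAPT_assessment": {
        "L3_IAPT_therapy": 0.5,
        "L3_IAPT_social_prescribing": 0.35,
        EXIT: 0.15,
    },
    "L3_IAPT_social_prescribing": {"L3_IAPT_therapy": 0.3, EXIT: 0.7},
    "L3_IAPT_therapy": {"L4_MHP_general": 0.35, EXIT: 0.65},
    "L4_MHP_triage": {
        "L4_MHP_general": 0.3,
        "L4_MHP_specialist": 0.3,
        "L4_MHP_crisis": 0.3,
        EXIT: 0.1,
    },
    "L4_MHP_general": {"L4_MHP_specialist": 0.25, "L4_MHP_crisis": 0.2, EXIT: 0.55},
    "L4_MHP_specialist": {
        "L5_AWP_inpatient": 0.3,
        "L4_MHP_general": 0.15,
        "L4_MHP_crisis": 0.05,
        EXIT: 0.5,
    },
    "L4_MHP_crisis": {"L5_AWP_inpatient": 0.45, "L4_MHP_general": 0.1, EXIT: 0.45},
    "L5_AWP_inpatient": {"L4_MHP_specialist": 0.3, "L4_MHP_crisis": 0.2, EXIT: 0.5},
}

# Mean stay in days and log-sd per service; community specialist care is the
# long-stay service (78 weeks = 546 days).
_DEFAULT_LOS: dict[str, tuple[float, float]] = {
    "L2_GP_high": (14.0, 0.8),
    "L2_GP_low": (7.0, 0.8),
    "L3_IAPT_assessment": (7.0, 0.5),
    "L3_IAPT_social_prescribing": (42.0, 0.6),
    "L3_IAPT_therapy": (63.0, 0.6),
    "L4_MHP_general": (120.0, 0.7),
    "L4_MHP_specialist": (546.0, 0.5),
    "L4_MHP_crisis": (14.0, 0.6),
    "L4_MHP_triage": (7.0, 0.5),
    "L5_AWP_inpatient": (30.0, 0.7),
}

# Escalation target when reneging from each service's queue; half of
# reneging patients escalate, half exit untreated.  Crisis escalates to
# inpatient; inpatient reneging always exits.
_DEFAULT_RENEGE: dict[str, tuple[int, str | None]] = {
    "L2_GP_high": (14, "L4_MHP_triage"),
    "L2_GP_low": (14, "L2_GP_high"),
    "L3_IAPT_assessment": (28, "L2_GP_high"),
    "L3_IAPT_social_prescribing": (28, "L2_GP_high"),
    "L3_IAPT_therapy": (28, "L2_GP_high"),
    "L4_MHP_general": (28, "L4_MHP_crisis"),
    "L4_MHP_specialist": (28, "L4_MHP_crisis"),
    "L4_MHP_crisis": (7, "L5_AWP_inpatient"),
    "L4_MHP_triage": (14, "L4_MHP_crisis"),
    "L5_AWP_inpatient": (7, None),
}

#: Headroom applied to steady-state occupancy when deriving default capacities.
DEFAULT_CAPACITY_HEADROOM = 1.15


def default_parameters(
    *,
    capacity_headroom: float = DEFAULT_CAPACITY_HEADROOM,
    with_renege: bool = True,
    unlimited_capacity: bool = False,
) -> ModelParameters:
    """Illustrative parameters for the ten-service system.

    The real system's arrival rates, stays and capacities are not public, so
    these defaults are synthetic: demand enters through general practice at a
    scaled-down rate, stays are lognormal with service-specific means, and
    capacities are set from the open-network traffic equations
    (``lambda_eff * mean_LOS``) with ``capacity_headroom`` slack, so the
    unstressed system runs just below saturation and pandemic-style demand
    surges produce queues and reneging.
    """
    services: dict[str, ServiceParams] = {}
    for sid in SERVICES:
        mean_days, sigma = _DEFAULT_LOS[sid]
        threshold, escalate_to = _DEFAULT_RENEGE[sid]
        renege = None
        if with_renege:
            dest = {EXIT: 1.0} if escalate_to is None else {escalate_to: 0.5, EXIT: 0.5}
            renege = RenegeConfig(threshold_days=threshold, hazard=1.0, destinations=dest)
        services[sid] = ServiceParams(
            service_id=sid,
            level=level_of(sid),
            arrival_rate=_DEFAULT_EXTERNAL_RATES.get(sid, 0.0),
            los=LosDistribution.lognormal_from_mean(mean_days, sigma),
            transitions=dict(_DEFAULT_TRANSITIONS[sid]),
            capacity=math.inf,
            renege=renege,
        )
    params = ModelParameters(services)
    if not unlimited_capacity:
        lam_eff = params.effective_arrival_rates()
        for sid, sp in params.services.items():
            occupancy = lam_eff[sid] * sp.los.mean_days()
            sp.capacity = float(max(1, math.ceil(occupancy * capacity_headroom)))
    return params
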