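"""Demand scenarios and mitigation interventions.

A scenario couples a *demand trajectory* -- piecewise-constant multipliers
on the external arrival rates, anchored to calendar dates -- with an
optional *intervention*: windowed capacity factors, length-of-stay scaling
(relative factor or absolute target), and transition-flow multipliers.

Four presets ship with the package, reflecting two published post-pandemic
demand hypotheses and one mitigation package for each:

* ``baseline_a`` -- demand doubles from April 2021 for GP, crisis and
  inpatient care (levels 2, 3 and 5), reverting in October 2021; IAPT
  assessment drops 20% from April 2021 then rises 25% from April 2022,
  reverting in October 2022.
* ``baseline_b`` -- fiscal-year demand uplifts: primary mental health
  +22%/+20%/+12% over 2020/21-2022/23, secondary care +25%/+24%/+14%,
  crisis +13%/+12%/+7%, specialist inpatient +1% in 2021/22.
* ``intervention_a`` -- baseline A demand plus 30% more level-2 (GP)
  capacity (April 2021 - October 2022) and a 20% shorter stay in IAPT
  therapy and the level-4 services (April - October 2022).
* ``intervention_b`` -- baseline B demand plus intervention A's measures,
  20%/30% more capacity at MHP general/specialist, specialist stays cut
  from 78 to 70 weeks, and 30% more flow from MHP specialist to MHP
  general and crisis (April 2021 - October 2022).

``intervention_a_table1`` is a narrower variant of intervention A whose
LOS cut applies to IAPT therapy only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .los import DAYS_PER_WEEK
from .params import ModelParameters, WindowedFactor, WindowedFlowFactor
from .simulate import MEASURES, ExperimentSummary, run_experiment

DEFAULT_REFERENCE_DATE = date(2021, 4, 1)


@dataclass(frozen=True)
class DemandSegment:
    """A multiplicative demand adjustment for a set of services on [start, end)."""

    services: tuple[str, ...]
    start: date
    end: date
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("demand multiplier must be positive")
        if self.start >= self.end:
            raise ValueError("segment start must precede end")


@dataclass(frozen=True)
class CapacityChange:
    services: tuple[str, ...]
    factor: float
    start: date
    end: date


@dataclass(frozen=True)
class LosChange:
    """LOS scaling: either a relative ``factor`` or an absolute
    ``target_mean_weeks`` resolved against the baseline mean at apply time."""

    services: tuple[str, ...]
    start: date
    end: date
    factor: float | None = None
    target_mean_weeks: float | None = None

    def __post_init__(self) -> None:
        if (self.factor is None) == (self.target_mean_weeks is None):
            raise ValueError("exactly one of factor / target_mean_weeks must be given")


@dataclass(frozen=True)
class FlowChange:
    source: str
    target: str
    factor: float
    start: date
    end: date


@dataclass
class InterventionSpec:
    """A bundle of windowed capacity, LOS and flow modifiers."""

    capacity: list[CapacityChange] = field(default_factory=list)
    los: list[LosChange] = field(default_factory=list)
    flow: list[FlowChange] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.capacity or self.los or self.flow)


@dataclass
class ScenarioSpec:
    """A named demand trajectory with an optional intervention."""

    name: str
    demand_segments: list[DemandSegment] = field(default_factory=list)
    intervention: InterventionSpec | None = None
    reference_date: date = DEFAULT_REFERENCE_DATE

    # -- demand ------------------------------------------------------------

    def multiplier(self, service_id: str, when: date) -> float:
        m = 1.0
        for seg in self.demand_segments:
            if service_id in seg.services and seg.start <= when < seg.end:
                m *= seg.multiplier
        return m

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "reference_date": self.reference_date.isoformat(),
            "demand_segments": [
                {
                    "services": list(seg.services),
                    "start": seg.start.isoformat(),
                    "end": seg.end.isoformat(),
                    "multiplier": seg.multiplier,
                }
                for seg in self.demand_segments
            ],
        }
        if self.intervention is not None and not self.intervention.is_empty():
            iv = self.intervention
            out["intervention"] = {
                "capacity": [
                    {
                        "services": list(c.services),
                        "factor": c.factor,
                        "start": c.start.isoformat(),
                        "end": c.end.isoformat(),
                    }
                    for c in iv.capacity
                ],
                "los": [
                    {
                        "services": list(c.services),
                        **(
                            {"factor": c.factor}
                            if c.factor is not None
                            else {"target_mean_weeks": c.target_mean_weeks}
                        ),
                        "start": c.start.isoformat(),
                        "end": c.end.isoformat(),
                    }
                    for c in iv.los
                ],
                "flow": [
                    {
                        "source": c.source,
                        "target": c.target,
                        "factor": c.factor,
                        "start": c.start.isoformat(),
                        "end": c.end.isoformat(),
                    }
                    for c in iv.flow
                ],
            }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        def _date(v) -> date:
            return v if isinstance(v, date) else date.fromisoformat(str(v))

        segments = [
            DemandSegment(
                services=tuple(seg["services"]),
                start=_date(seg["start"]),
                end=_date(seg["end"]),
                multiplier=float(seg["multiplier"]),
            )
            for seg in data.get("demand_segments", [])
        ]
        intervention = None
        if data.get("intervention"):
            iv = data["intervention"]
            intervention = InterventionSpec(
                capacity=[
                    CapacityChange(
                        services=tuple(c["services"]),
                        factor=float(c["factor"]),
                        start=_date(c["start"]),
                        end=_date(c["end"]),
                    )
                    for c in iv.get("capacity", [])
                ],
                los=[
                    LosChange(
                        services=tuple(c["services"]),
                        factor=float(c["factor"]) if "factor" in c else None,
                        target_mean_weeks=(
                            float(c["target_mean_weeks"]) if "target_mean_weeks" in c else None
                        ),
                        start=_date(c["start"]),
                        end=_date(c["end"]),
                    )
                    for c in iv.get("los", [])
                ],
                flow=[
                    FlowChange(
                        source=c["source"],
                        target=c["target"],
                        factor=float(c["factor"]),
                        start=_date(c["start"]),
                        end=_date(c["end"]),
                    )
                    for c in iv.get("flow", [])
                ],
            )
        ref = data.get("reference_date", DEFAULT_REFERENCE_DATE)
        return cls(
            name=data["name"],
            demand_segments=segments,
            intervention=intervention,
            reference_date=_date(ref),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_demand_profile(
    params: ModelParameters,
    scenario: ScenarioSpec,
    *,
    start_date: date,
    horizon_days: int,
) -> np.ndarray:
    """Time-varying external arrival rates, shape (horizon_days, n_services).

    ``lambda_s(t) = base_s x prod(multipliers of segments covering (s, t))``;
    piecewise-constant with jumps at segment boundaries.
    """
    ids = params.service_ids
    known = set(ids)
    base = np.array([params.services[s].arrival_rate for s in ids])
    out = np.tile(base, (horizon_days, 1))
    index = {s: j for j, s in enumerate(ids)}
    for seg in scenario.demand_segments:
        unknown = [s for s in seg.services if s not in known]
        if unknown:
            raise ValueError(f"demand segment names unknown service(s) {unknown}")
        a = max(0, (seg.start - start_date).days)
        b = min(horizon_days, (seg.end - start_date).days)
        if a >= b:
            continue
        for s in seg.services:
            out[a:b, index[s]] *= seg.multiplier
    return out


def apply_intervention(
    params: ModelParameters, intervention: InterventionSpec | None
) -> ModelParameters:
    """Return a copy of ``params`` with the intervention's windowed modifiers
    attached.

    Capacity and LOS factors multiply within their windows (capacities are
    rounded to whole slots, minimum one, at evaluation time); an absolute
    LOS target is converted to a factor against the baseline mean stay.
    Flow factors scale named transition edges, with the untouched edges
    renormalised proportionally so each row still sums to one.
    """
    out = params.copy()
    if intervention is None or intervention.is_empty():
        return out
    for change in intervention.capacity:
        for sid in change.services:
            _service(out, sid).capacity_factors.append(
                WindowedFactor(change.start, change.end, change.factor)
            )
    for change in intervention.los:
        for sid in change.services:
            sp = _service(out, sid)
            if change.factor is not None:
                factor = change.factor
            else:
                base_weeks = sp.los.mean_days() / DAYS_PER_WEEK
                factor = change.target_mean_weeks / base_weeks
            sp.los_factors.append(WindowedFactor(change.start, change.end, factor))
    for change in intervention.flow:
        sp = _service(out, change.source)
        if change.target not in sp.transitions:
            raise ValueError(
                f"flow change targets absent edge {change.source}->{change.target}"
            )
        sp.flow_factors.append(
            WindowedFlowFactor(change.target, change.start, change.end, change.factor)
        )
        # reject factors that push a single edge above probability one
        sp.transition_row_on(change.start)
    return out


def scale_relative(
    summary: ExperimentSummary, reference_date: date
) -> tuple[ExperimentSummary, list[tuple[str, str]]]:
    """Rescale every weekly series by its own value in the reference week.

    The reference week maps to 1.0, so later weeks read as demand relative
    to that timepoint.  Series whose reference value is zero cannot be
    scaled; they are set to NaN and reported in the flagged list as
    (measure, service) pairs.
    """
    ref_week = summary.week_of(reference_date)
    flagged: list[tuple[str, str]] = []
    measures: dict[str, dict[str, np.ndarray]] = {}
    for m, stats in summary.measures.items():
        measures[m] = {}
        for stat, arr in stats.items():
            scaled = np.empty_like(arr, dtype=float)
            for i, sid in enumerate(summary.services):
                ref = arr[i, ref_week]
                if ref == 0:
                    scaled[i] = np.nan
                    if stat == "mean":
                        flagged.append((m, sid))
                else:
                    scaled[i] = arr[i] / ref
            measures[m][stat] = scaled
    out = ExperimentSummary(
        services=list(summary.services),
        start_date=summary.start_date,
        horizon_days=summary.horizon_days,
        warmup_weeks=summary.warmup_weeks,
        n_replications=summary.n_replications,
        seeds=list(summary.seeds),
        measures=measures,
    )
    return out, flagged


def compare_scenarios(
    baseline: ExperimentSummary,
    intervention: ExperimentSummary,
    *,
    window_start: date | None = None,
) -> pd.DataFrame:
    """Percentage change of intervention vs baseline per service and measure.

    Over the comparison window (from ``window_start``, or after warm-up),
    the max change is ``100 x (max(int) - max(base)) / max(base)`` and the
    mean change is the analogue on window means, both computed on the mean
    series across replications.  A zero baseline statistic yields a missing
    value rather than an infinity.
    """
    if baseline.services != intervention.services:
        raise ValueError("summaries cover different services")
    if (
        baseline.horizon_days != intervention.horizon_days
        or baseline.start_date != intervention.start_date
    ):
        raise ValueError("summaries cover different horizons")
    if window_start is not None:
        w0 = baseline.week_of(window_start)
    else:
        w0 = baseline.warmup_weeks
    rows = []
    for m in MEASURES:
        base_arr = baseline.series(m)[:, w0:]
        int_arr = intervention.series(m)[:, w0:]
        for i, sid in enumerate(baseline.services):
            b_max, i_max = base_arr[i].max(), int_arr[i].max()
            b_mean, i_mean = base_arr[i].mean(), int_arr[i].mean()
            rows.append(
                {
                    "service": sid,
                    "measure": m,
                    "max_pct_change": (
                        100.0 * (i_max - b_max) / b_max if b_max > 0 else np.nan
                    ),
                    "mean_pct_change": (
                        100.0 * (i_mean - b_mean) / b_mean if b_mean > 0 else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows, columns=["service", "measure", "max_pct_change", "mean_pct_change"])


def run_scenario(
    params: ModelParameters,
    scenario: ScenarioSpec,
    *,
    start_date: date,
    horizon_days: int,
    n_replications: int,
    base_seed: int,
    warmup_weeks: int = 0,
    warm_start: bool = False,
    keep_replications: bool = False,
):
    """Apply a scenario to the parameters and run a replicated experiment."""
    modified = apply_intervention(params, scenario.intervention)
    demand = build_demand_profile(
        modified, scenario, start_date=start_date, horizon_days=horizon_days
    )
    return run_experiment(
        modified,
        start_date=start_date,
        horizon_days=horizon_days,
        n_replications=n_replications,
        base_seed=base_seed,
        demand=demand,
        warmup_weeks=warmup_weeks,
        warm_start=warm_start,
        keep_replications=keep_replications,
    )


def _service(params: ModelParameters, sid: str):
    try:
        return params.services[sid]
    except KeyError:
        raise ValueError(f"intervention names unknown service {sid!r}") from None


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "baseline_a",
    "baseline_b",
    "intervention_a",
    "intervention_a_table1",
    "intervention_b",
)


def load_preset(name: str) -> ScenarioSpec:
    """Load one packaged scenario preset by name."""
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
    text = resources.files("careflow").joinpath(f"presets/{name}.yaml").read_text()
    return ScenarioSpec.from_dict(yaml.safe_load(text))


def preset_scenarios() -> dict[str, ScenarioSpec]:
    """All packaged scenario presets, keyed by name."""
    return {name: load_preset(name) for name in PRESET_NAMES}
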