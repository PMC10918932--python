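"""Process mining: from a discrete event log to pathways, a transition
network, and simulation parameters.

Care episodes are recorded as separate rows in the activity table; this
module reassembles them into per-patient pathways (causally ordered
sequences of episodes), aggregates the pathways into a service-transition
network, and estimates the flow parameters the simulator consumes: external
arrival rates, length-of-stay distributions, transition probabilities,
waiting times, and reneging rates.

A *pathway* ends when an episode's outcome is ``discharged`` or
``reneged_exited``; a later record for the same patient is a new external
arrival.  ``transferred`` and ``reneged_escalated`` continue the pathway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .los import DAYS_PER_WEEK, LosDistribution
from .params import ModelParameters, RenegeConfig, ServiceParams
from .services import EXIT, SERVICE_LEVELS
from .severity import SeverityConfig, classify_severity

__all__ = [
    "PathwayStep",
    "PathwaySequence",
    "PathwayGraph",
    "ParameterEstimates",
    "reconstruct_pathways",
    "build_pathway_graph",
    "estimate_parameters",
    "cohort_summary",
    "attendance_shares",
    "referral_window_share",
    "classify_severity",
]

_EXIT_OUTCOMES = frozenset({"discharged", "reneged_exited"})
_CONTINUE_OUTCOMES = frozenset({"transferred", "reneged_escalated"})
_COMPLETED_OUTCOMES = frozenset({"transferred", "discharged"})


class PathwayStep(NamedTuple):
    service_id: str
    referral_date: pd.Timestamp
    start_date: pd.Timestamp  # NaT for queue spells that ended in reneging
    end_date: pd.Timestamp  # NaT for censored episodes
    outcome: str


@dataclass
class PathwaySequence:
    """One patient's causally ordered episode sequence."""

    patient_id: str
    steps: list[PathwayStep]

    def __len__(self) -> int:
        return len(self.steps)

    def services(self) -> list[str]:
        return [s.service_id for s in self.steps]


def reconstruct_pathways(activity: pd.DataFrame) -> list[PathwaySequence]:
    """Group the event log into one ordered sequence per patient.

    Steps are sorted by start date (falling back to referral date for queue
    spells without a start), with file order as the intra-day tiebreak.
    Overlapping episodes -- which the one-service-at-a-time flow model
    excludes -- are repaired by truncating the earlier episode at the later
    episode's start, with a single summary warning.
    """
    frame = activity.copy()
    frame["_order_date"] = frame["start_date"].fillna(frame["referral_date"])
    frame["_row"] = np.arange(len(frame))
    frame = frame.sort_values(
        ["patient_id", "_order_date", "referral_date", "_row"], kind="stable"
    )

    truncated = 0
    sequences: list[PathwaySequence] = []
    pids = frame["patient_id"].tolist()
    services = frame["service_id"].tolist()
    referrals = frame["referral_date"].tolist()
    starts = frame["start_date"].tolist()
    ends = frame["end_date"].tolist()
    outcomes = frame["outcome"].tolist()
    # group boundaries over the sorted patient column
    bounds = [0] + [i for i in range(1, len(pids)) if pids[i] != pids[i - 1]] + [len(pids)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        steps = [
            PathwayStep(services[i], referrals[i], starts[i], ends[i], outcomes[i])
            for i in range(a, b)
        ]
        # repair overlaps against the model's one-service-at-a-time assumption
        for i in range(len(steps) - 1):
            cur, nxt = steps[i], steps[i + 1]
            if (
                pd.notna(cur.end_date)
                and pd.notna(nxt.start_date)
                and cur.end_date > nxt.start_date
            ):
                steps[i] = cur._replace(end_date=nxt.start_date)
                truncated += 1
        sequences.append(PathwaySequence(patient_id=pids[a], steps=steps))

    if truncated:
        warnings.warn(
            f"truncated {truncated} overlapping episode(s) at the next episode's start",
            stacklevel=2,
        )
    return sequences


# ---------------------------------------------------------------------------
# pathway graph
# ---------------------------------------------------------------------------


@dataclass
class PathwayGraph:
    """Service-transition network mined from pathways.

    Nodes are services (plus the ``exit`` sink) annotated with activity
    counts and relative frequency (% of all episodes); directed edges carry
    transition counts, relative frequency (% of all transitions) and the
    median inter-activity gap in weeks.
    """

    graph: nx.DiGraph
    total_activity: int
    total_transitions: int

    def node_frame(self) -> pd.DataFrame:
        rows = [
            {
                "service": n,
                "count": d.get("count", 0),
                "rel_freq_pct": d.get("rel_freq_pct", 0.0),
            }
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows).sort_values("service").reset_index(drop=True)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "count": d["count"],
                "rel_freq_pct": d["rel_freq_pct"],
                "median_gap_weeks": d["median_gap_weeks"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return (
            pd.DataFrame(rows, columns=["source", "target", "count", "rel_freq_pct", "median_gap_weeks"])
            .sort_values(["source", "target"])
            .reset_index(drop=True)
        )

    def to_csv(self, path) -> None:
        self.edge_frame().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            if d.get("median_gap_weeks") is None or (
                isinstance(d.get("median_gap_weeks"), float) and math.isnan(d["median_gap_weeks"])
            ):
                d["median_gap_weeks"] = -1.0
        nx.write_graphml(g, path)


def build_pathway_graph(sequences: list[PathwaySequence]) -> PathwayGraph:
    """Aggregate pathways into the transition network.

    An edge a->b is counted whenever episode b directly follows episode a
    within one pathway, regardless of the time gap; pathway-ending episodes
    contribute an edge to the ``exit`` sink.  The edge gap statistic is the
    median of (start of b - end of a) in weeks.
    """
    if not sequences:
        raise ValueError("cannot build a pathway graph from zero sequences")
    node_counts: dict[str, int] = {}
    edge_counts: dict[tuple[str, str], int] = {}
    edge_gaps: dict[tuple[str, str], list[float]] = {}

    for seq in sequences:
        steps = seq.steps
        for i, step in enumerate(steps):
            node_counts[step.service_id] = node_counts.get(step.service_id, 0) + 1
            nxt: str | None
            if step.outcome in _EXIT_OUTCOMES:
                nxt = EXIT
            elif step.outcome in _CONTINUE_OUTCOMES and i + 1 < len(steps):
                nxt = steps[i + 1].service_id
            else:  # censored, or a dangling 'transferred' at the table edge
                nxt = EXIT if step.outcome == "transferred" and i + 1 == len(steps) else None
                if step.outcome == "censored":
                    nxt = None
            if nxt is None:
                continue
            key = (step.service_id, nxt)
            edge_counts[key] = edge_counts.get(key, 0) + 1
            if nxt != EXIT:
                nxt_start = steps[i + 1].start_date
                prev_end = step.end_date
                if pd.notna(nxt_start) and pd.notna(prev_end):
                    edge_gaps.setdefault(key, []).append(
                        (nxt_start - prev_end).days / DAYS_PER_WEEK
                    )

    total_activity = sum(node_counts.values())
    total_transitions = sum(edge_counts.values())
    g = nx.DiGraph()
    for sid, count in node_counts.items():
        g.add_node(sid, count=count, rel_freq_pct=100.0 * count / total_activity)
    if any(v == EXIT for _, v in edge_counts):
        g.add_node(EXIT, count=0, rel_freq_pct=0.0)
    for (u, v), count in edge_counts.items():
        gaps = edge_gaps.get((u, v))
        g.add_edge(
            u,
            v,
            count=count,
            rel_freq_pct=100.0 * count / total_transitions,
            median_gap_weeks=float(np.median(gaps)) if gaps else float("nan"),
        )
    return PathwayGraph(graph=g, total_activity=total_activity, total_transitions=total_transitions)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


@dataclass
class ParameterEstimates:
    """Flow parameters estimated from mined pathways.

    ``los_days`` and ``wait_days`` hold empirical samples; ``renege_rate``
    is reneges per waiting patient-week.  ``flagged_services`` lists
    services with zero completed episodes, whose transition row fell back
    to exit-with-probability-one.
    """

    services: list[str]
    horizon_days: float
    arrival_rate: dict[str, float]  # external arrivals/day
    transition_probs: pd.DataFrame  # index services, columns services + exit
    los_days: dict[str, np.ndarray]
    wait_days: dict[str, np.ndarray]
    renege_rate: dict[str, float]  # per waiting patient per week
    flagged_services: list[str] = field(default_factory=list)

    def mean_los_weeks(self, service_id: str) -> float:
        values = self.los_days[service_id]
        return float(np.mean(values)) / DAYS_PER_WEEK if values.size else float("nan")

    def fit_lognormal_los(self, service_id: str) -> LosDistribution:
        """Lognormal LOS by matching log-moments of the empirical sample."""
        values = self.los_days[service_id]
        if values.size < 2:
            raise ValueError(f"not enough completed episodes in {service_id} to fit")
        logs = np.log(np.maximum(values, 0.5))
        return LosDistribution("lognormal", {"mu": float(logs.mean()), "sigma": float(logs.std(ddof=1))})

    def to_model_parameters(
        self,
        *,
        los_family: str = "empirical",
        capacities: dict[str, float] | None = None,
        renege: dict[str, RenegeConfig] | None = None,
    ) -> ModelParameters:
        """Package the estimates in the simulator's parameter schema.

        Capacities and reneging configuration are not identifiable from a
        capacity-free log, so they are supplied (or left unlimited / absent).
        """
        services: dict[str, ServiceParams] = {}
        for sid in self.services:
            if los_family == "lognormal" and self.los_days[sid].size >= 2:
                los = self.fit_lognormal_los(sid)
            elif self.los_days[sid].size:
                los = LosDistribution("empirical", {"values": self.los_days[sid].tolist()})
            else:
                los = LosDistribution("fixed", {"days": 1})
            row = self.transition_probs.loc[sid]
            transitions = {k: float(v) for k, v in row.items() if v > 0}
            services[sid] = ServiceParams(
                service_id=sid,
                level=SERVICE_LEVELS.get(sid, 0),
                arrival_rate=self.arrival_rate[sid],
                los=los,
                transitions=transitions,
                capacity=(capacities or {}).get(sid, math.inf),
                renege=(renege or {}).get(sid),
            )
        return ModelParameters(services)


def estimate_parameters(
    sequences: list[PathwaySequence],
    *,
    horizon_days: float | None = None,
) -> ParameterEstimates:
    """Estimate arrival, stay, transition, wait and renege parameters.

    External arrivals are pathway-initiating episodes: a patient's first
    record, or any record following a pathway exit (discharge or renege-out).
    Transition rows are estimated over completed episodes only, so censored
    episodes do not bias the routing probabilities.
    """
    if not sequences:
        raise ValueError("no pathways supplied")

    service_set: set[str] = set()
    for seq in sequences:
        service_set.update(seq.services())
    services = sorted(service_set)
    s_index = {s: i for i, s in enumerate(services)}
    n = len(services)

    arrivals = np.zeros(n)
    trans_counts = np.zeros((n, n + 1))
    los_samples: dict[str, list[float]] = {s: [] for s in services}
    wait_samples: dict[str, list[float]] = {s: [] for s in services}
    renege_events = np.zeros(n)
    waiting_days = np.zeros(n)

    first_date: pd.Timestamp | None = None
    last_date: pd.Timestamp | None = None

    for seq in sequences:
        new_pathway = True
        steps = seq.steps
        for i, step in enumerate(steps):
            si = s_index[step.service_id]
            if new_pathway:
                arrivals[si] += 1
            new_pathway = step.outcome in _EXIT_OUTCOMES

            for stamp in (step.referral_date, step.start_date, step.end_date):
                if pd.isna(stamp):
                    continue
                if first_date is None or stamp < first_date:
                    first_date = stamp
                if last_date is None or stamp > last_date:
                    last_date = stamp

            if step.outcome in _COMPLETED_OUTCOMES:
                if step.outcome == "discharged":
                    trans_counts[si, n] += 1
                elif i + 1 < len(steps):
                    trans_counts[si, s_index[steps[i + 1].service_id]] += 1
                else:  # transfer whose destination fell outside the table
                    trans_counts[si, n] += 1
                if pd.notna(step.start_date) and pd.notna(step.end_date):
                    los_samples[step.service_id].append((step.end_date - step.start_date).days)

            if pd.notna(step.start_date) and pd.notna(step.referral_date):
                wait = (step.start_date - step.referral_date).days
                wait_samples[step.service_id].append(wait)
                waiting_days[si] += wait
            if step.outcome in ("reneged_escalated", "reneged_exited"):
                renege_events[si] += 1
                if pd.notna(step.end_date) and pd.notna(step.referral_date):
                    waiting_days[si] += (step.end_date - step.referral_date).days

    if horizon_days is None:
        if first_date is None:
            raise ValueError("pathways contain no dates")
        horizon_days = (last_date - first_date).days + 1

    flagged: list[str] = []
    probs = np.zeros_like(trans_counts)
    for i, sid in enumerate(services):
        total = trans_counts[i].sum()
        if total == 0:
            flagged.append(sid)
            probs[i, n] = 1.0  # exit-with-probability-one fallback
        else:
            probs[i] = trans_counts[i] / total

    waiting_weeks = waiting_days / DAYS_PER_WEEK
    renege_rate = {
        sid: float(renege_events[i] / waiting_weeks[i]) if waiting_weeks[i] > 0 else 0.0
        for i, sid in enumerate(services)
    }

    return ParameterEstimates(
        services=services,
        horizon_days=float(horizon_days),
        arrival_rate={s: float(arrivals[i] / horizon_days) for i, s in enumerate(services)},
        transition_probs=pd.DataFrame(probs, index=services, columns=services + [EXIT]),
        los_days={s: np.asarray(v, dtype=float) for s, v in los_samples.items()},
        wait_days={s: np.asarray(v, dtype=float) for s, v in wait_samples.items()},
        renege_rate=renege_rate,
        flagged_services=flagged,
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

_SUMMARY_ATTRIBUTES = ("sex", "age_band", "ethnicity", "ses_quintile")


def cohort_summary(
    attributes: pd.DataFrame,
    activity: pd.DataFrame,
    *,
    severity_config: SeverityConfig | None = None,
) -> pd.DataFrame:
    """Per-service demographic breakdown: counts and one-decimal percentages.

    For each service, patients are those with at least one activity record
    there; the percentage denominator is the number of those patients with a
    known value for the attribute.  If a severity configuration is given, a
    severity breakdown (from condition flags) is included.
    """
    attrs = attributes.set_index("patient_id")
    if severity_config is not None:
        attrs = attrs.copy()
        attrs["severity"] = [
            classify_severity(
                [c for c in str(flags).split(";") if c], severity_config
            )
            for flags in attrs["condition_flags"]
        ]

    rows: list[dict] = []
    breakdown_attrs = _SUMMARY_ATTRIBUTES + (("severity",) if severity_config else ())
    for sid, group in activity.groupby("service_id", sort=True):
        patient_ids = group["patient_id"].unique()
        present = attrs.reindex(patient_ids)
        n_patients = len(patient_ids)
        rows.append(
            {
                "service": sid,
                "attribute": "_patients",
                "category": "N",
                "count": n_patients,
                "pct": 100.0,
            }
        )
        for attr in breakdown_attrs:
            col = present[attr].dropna()
            denom = len(col)
            for category, count in col.value_counts().sort_index().items():
                rows.append(
                    {
                        "service": sid,
                        "attribute": attr,
                        "category": str(category),
                        "count": int(count),
                        "pct": round(100.0 * count / denom, 1) if denom else float("nan"),
                    }
                )
    return pd.DataFrame(rows, columns=["service", "attribute", "category", "count", "pct"])


def attendance_shares(activity: pd.DataFrame) -> pd.DataFrame:
    """Attendance counts and one-decimal percentage shares per care level."""
    counts = activity.groupby("level").size()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "level": counts.index.to_numpy(),
            "attendances": counts.to_numpy(),
            "pct": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    )


def referral_window_share(
    activity: pd.DataFrame, start: pd.Timestamp, end: pd.Timestamp
) -> dict[str, float]:
    """Share of activity referred within [start, end).

    Reported against both denominators -- distinct patients and attendances
    -- because the two give materially different percentages.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    in_window = (activity["referral_date"] >= start) & (activity["referral_date"] < end)
    n_patients = activity["patient_id"].nunique()
    patients_in_window = activity.loc[in_window, "patient_id"].nunique()
    return {
        "patients_in_window": int(patients_in_window),
        "pct_of_patients": round(100.0 * patients_in_window / n_patients, 1),
        "attendances_in_window": int(in_window.sum()),
        "pct_of_attendances": round(100.0 * in_window.sum() / len(activity), 1),
    }
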