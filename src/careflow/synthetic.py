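"""Synthetic patient-level data with known ground truth.

The real system's linked attribute/activity tables are confidential, so
every downstream stage (process mining, simulation, scenario analysis) is
exercised on synthetic cohorts generated here from a known
:class:`~careflow.params.ModelParameters` ground truth:

* an **attributes table** -- one row per patient with demographics and
  condition flags drawn from configurable category weights;
* an **activity table** (event log) -- one row per service episode, with
  referral/start/end dates and an outcome, produced by walking the
  ground-truth transition chain with Poisson external arrivals and
  per-service length-of-stay draws.

By default generation is *capacity-free*: queues never form and
``start_date == referral_date``, so parameters mined from the log can be
compared to the ground truth without queueing bias.  A capacity-constrained
mode runs the full simulator with event tracing instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParameters, default_parameters
from .services import EXIT, SERVICE_LEVELS
from .severity import SEVERITY_METHODS_TEXT, SeverityConfig
from .simulate import Simulation

WEIGHT_TOL = 1e-9

ACTIVITY_COLUMNS = [
    "patient_id",
    "service_id",
    "level",
    "referral_date",
    "start_date",
    "end_date",
    "outcome",
]

ATTRIBUTE_COLUMNS = [
    "patient_id",
    "sex",
    "age_band",
    "ethnicity",
    "ses_quintile",
    "condition_flags",
]

OUTCOMES = (
    "transferred",
    "discharged",
    "reneged_escalated",
    "reneged_exited",
    "censored",
)

#: Default attribute category weights, patterned on the cohort's overall
#: demographic mix (predominantly female, white, aged 40-59).
DEFAULT_CATEGORY_WEIGHTS: dict[str, dict] = {
    "sex": {"female": 0.619, "male": 0.381},
    "age_band": {"18-29": 0.25, "30-39": 0.21, "40-59": 0.30, "60-79": 0.17, "80-90+": 0.07},
    "ethnicity": {
        "white": 0.85,
        "mixed": 0.065,
        "asian": 0.027,
        "black": 0.026,
        "other": 0.032,
    },
    "ses_quintile": {1: 0.21, 2: 0.19, 3: 0.17, 4: 0.21, 5: 0.22},
    # marginal probability that a patient carries >= 1 chronic / associated code
    "severity": {"severe": 0.15, "moderate": 0.70, "mild": 0.15},
}


@dataclass
class SyntheticCohortSpec:
    """Recipe for one synthetic cohort.

    ``ground_truth`` drives the event-log generator; ``category_weights``
    drive the attribute generator.  All randomness flows from ``seed``.
    """

    n_patients: int = 1000
    start: date = date(2019, 4, 1)
    end: date = date(2021, 4, 1)
    category_weights: dict = field(default_factory=lambda: _copy_weights(DEFAULT_CATEGORY_WEIGHTS))
    ground_truth: ModelParameters | None = None
    severity_codes: SeverityConfig = SEVERITY_METHODS_TEXT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.start >= self.end:
            raise ValueError("horizon start must precede end")
        for attr, weights in self.category_weights.items():
            total = sum(weights.values())
            if abs(total - 1.0) > WEIGHT_TOL:
                raise ValueError(
                    f"category weights for {attr!r} sum to {total!r}, expected 1"
                )
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative weight in {attr!r}")
        if self.ground_truth is None:
            self.ground_truth = default_parameters()

    @property
    def horizon_days(self) -> int:
        return (self.end - self.start).days


def _copy_weights(weights: dict) -> dict:
    return {k: dict(v) for k, v in weights.items()}


def _pid(i: int) -> str:
    return f"P{i:07d}"


# ---------------------------------------------------------------------------
# attributes
# ---------------------------------------------------------------------------


def generate_attributes(
    spec: SyntheticCohortSpec, patient_ids: list[str] | None = None
) -> pd.DataFrame:
    """Generate the patient attributes table.

    One row per patient; attribute frequencies converge to the spec's
    category weights as the cohort grows.  If ``patient_ids`` is given the
    table covers exactly those patients (e.g. the patients of a generated
    event log); otherwise ``spec.n_patients`` fresh ids are created.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if patient_ids is None:
        patient_ids = [_pid(i) for i in range(spec.n_patients)]
    n = len(patient_ids)

    columns: dict[str, np.ndarray] = {"patient_id": np.array(patient_ids, dtype=object)}
    for attr in ("sex", "age_band", "ethnicity", "ses_quintile"):
        weights = spec.category_weights[attr]
        cats = np.array(list(weights), dtype=object)
        probs = np.array(list(weights.values()), dtype=float)
        columns[attr] = cats[rng.choice(len(cats), size=n, p=probs / probs.sum())]

    sev_weights = spec.category_weights["severity"]
    sev_cats = np.array(list(sev_weights), dtype=object)
    sev_probs = np.array(list(sev_weights.values()), dtype=float)
    severity = sev_cats[rng.choice(len(sev_cats), size=n, p=sev_probs / sev_probs.sum())]
    severe_codes = sorted(spec.severity_codes.severe)
    moderate_codes = sorted(spec.severity_codes.moderate)
    flags = []
    for s in severity:
        if s == "severe":
            flags.append(severe_codes[rng.integers(len(severe_codes))])
        elif s == "moderate":
            flags.append(moderate_codes[rng.integers(len(moderate_codes))])
        else:
            flags.append("")
    columns["condition_flags"] = np.array(flags, dtype=object)

    frame = pd.DataFrame(columns, columns=ATTRIBUTE_COLUMNS)
    frame["ses_quintile"] = frame["ses_quintile"].astype(np.int64)
    return frame


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------


def generate_event_log(
    spec: SyntheticCohortSpec, *, capacity_constrained: bool = False
) -> pd.DataFrame:
    """Generate the activity table (event log).

    External arrivals at each service are Poisson with the ground-truth
    daily rate; each patient then walks the ground-truth transition chain,
    drawing a length of stay per episode.  In the default capacity-free
    mode every referral starts the same day; with
    ``capacity_constrained=True`` the full simulator (capacity gates, FIFO
    queues, reneging) is run with event tracing instead.

    Episodes still open at the horizon are emitted with a missing end date
    and outcome ``censored``.
    """
    params = spec.ground_truth
    params.validate()
    if capacity_constrained:
        sim = Simulation(
            params,
            start_date=spec.start,
            horizon_days=spec.horizon_days,
            seed=spec.seed,
            trace=True,
        )
        sim.run()
        return sim.event_log()

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    ids = params.service_ids
    n = len(ids)
    horizon = spec.horizon_days

    # per-service routing tables (base rows; generation is scenario-free)
    dest_tables = []
    for sid in ids:
        row = params.services[sid].transitions
        idx = {s: j for j, s in enumerate(ids)}
        dests = np.array([n if d == EXIT else idx[d] for d in row], dtype=np.int64)
        cums = np.cumsum(np.array(list(row.values())))
        dest_tables.append((dests, cums))
    los_dists = [params.services[sid].los for sid in ids]

    # external arrivals, one Poisson draw per service over the horizon
    arrival_days: list[np.ndarray] = []
    arrival_services: list[np.ndarray] = []
    for j, sid in enumerate(ids):
        rate = params.services[sid].arrival_rate
        counts = rng.poisson(rate, horizon)
        days = np.repeat(np.arange(horizon), counts)
        arrival_days.append(days)
        arrival_services.append(np.full(days.size, j, dtype=np.int64))
    days_all = np.concatenate(arrival_days) if arrival_days else np.array([], dtype=int)
    svcs_all = np.concatenate(arrival_services) if arrival_services else np.array([], dtype=int)
    # stable chronological patient numbering
    order = np.argsort(days_all, kind="stable")
    days_all, svcs_all = days_all[order], svcs_all[order]

    records: list[tuple] = []
    for pid_i, (day0, s0) in enumerate(zip(days_all, svcs_all)):
        s = int(s0)
        day = int(day0)
        while True:
            los = int(los_dists[s].sample_days(rng, 1)[0])
            end = day + los
            if end >= horizon:
                records.append((pid_i, s, day, day, None, "censored"))
                break
            dests, cums = dest_tables[s]
            nxt = int(dests[int(np.searchsorted(cums, rng.random(), side="right"))])
            if nxt == n:
                records.append((pid_i, s, day, day, end, "discharged"))
                break
            records.append((pid_i, s, day, day, end, "transferred"))
            s = nxt
            day = end

    origin = pd.Timestamp(spec.start)

    def _dt(day):
        return origin + pd.Timedelta(days=day) if day is not None else pd.NaT

    frame = pd.DataFrame(
        [
            {
                "patient_id": _pid(pid_i),
                "service_id": ids[s],
                "level": SERVICE_LEVELS.get(ids[s], 0),
                "referral_date": _dt(ref),
                "start_date": _dt(start),
                "end_date": _dt(end),
                "outcome": outcome,
            }
            for pid_i, s, ref, start, end, outcome in records
        ],
        columns=ACTIVITY_COLUMNS,
    )
    return frame


def generate_cohort(spec: SyntheticCohortSpec, *, capacity_constrained: bool = False):
    """Generate a linked (attributes, activity) table pair.

    The attribute table covers exactly the patients appearing in the
    generated event log, so the two tables share patient ids.
    """
    activity = generate_event_log(spec, capacity_constrained=capacity_constrained)
    patient_ids = list(dict.fromkeys(activity["patient_id"]))
    attributes = generate_attributes(spec, patient_ids=patient_ids)
    return attributes, activity


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_event_log(records: pd.DataFrame, path: str | Path) -> None:
    """Write an activity table as CSV with ISO-8601 dates (open dates blank)."""
    out = records.copy()
    missing = [c for c in ACTIVITY_COLUMNS if c not in out.columns]
    if missing:
        raise ValueError(f"activity table missing columns {missing}")
    for col in ("referral_date", "start_date", "end_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out[ACTIVITY_COLUMNS].to_csv(path, index=False)


def read_event_log(path: str | Path) -> pd.DataFrame:
    """Read an activity CSV, validating dates and outcomes row by row."""
    frame = pd.read_csv(path, dtype={"patient_id": str, "service_id": str, "outcome": str})
    missing = [c for c in ACTIVITY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"activity file {path} missing columns {missing}")
    for col in ("referral_date", "start_date", "end_date"):
        raw = frame[col]
        parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"activity file {path}: row {row}, field {col!r}: "
                f"unparseable date {raw[row]!r}"
            )
        frame[col] = parsed
    bad_outcome = ~frame["outcome"].isin(OUTCOMES)
    if bad_outcome.any():
        row = int(bad_outcome.idxmax())
        raise ValueError(
            f"activity file {path}: row {row}, field 'outcome': "
            f"unknown value {frame['outcome'][row]!r}"
        )
    frame["level"] = frame["level"].astype(np.int64)
    return frame[ACTIVITY_COLUMNS]


def write_attributes(attributes: pd.DataFrame, path: str | Path) -> None:
    attributes[ATTRIBUTE_COLUMNS].to_csv(path, index=False)


def read_attributes(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"patient_id": str, "condition_flags": str})
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"attributes file {path} missing columns {missing}")
    frame["condition_flags"] = frame["condition_flags"].fillna("")
    frame["ses_quintile"] = frame["ses_quintile"].astype(np.int64)
    return frame[ATTRIBUTE_COLUMNS]
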