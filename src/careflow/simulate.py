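"""Discrete-time simulation of patient flow through capacity-constrained
services with FIFO queues and reneging.

The simulator advances in one-day steps.  Within each day, events are
resolved in a fixed order:

1. external arrivals (Poisson per service) join the service queue;
2. patients whose stay ends today leave, sampling a destination from the
   service's transition row -- transferees join the destination queue,
   the rest exit the pathway;
3. free capacity is filled from the head of each queue (first-come
   first-served); each admission samples a length of stay;
4. queued patients whose wait exceeds the renege threshold leave the queue
   with the configured per-day hazard, escalating to another service's
   queue or exiting untreated;
5. counters and wait clocks are updated.

Daily state is aggregated to weekly series (queue size and occupancy at
week end; renege counts summed per week).  Replications differ only by
seed; an experiment summarises them with the elementwise mean and the
empirical 2.5%/97.5% quantiles.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .params import ModelParameters
from .services import EXIT

MEASURES = ("queue_size", "occupancy", "renege_from", "renege_to")

_COUNTER_KEYS = (
    "initial",
    "external",
    "transfers_in",
    "reneges_in",
    "admissions",
    "completions",
    "transfers_out",
    "exits",
    "reneges_from",
    "renege_exits",
    "renege_escalations",
)

#: outcome labels used in traced event logs
OUTCOME_TRANSFERRED = "transferred"
OUTCOME_DISCHARGED = "discharged"
OUTCOME_RENEGED_ESCALATED = "reneged_escalated"
OUTCOME_RENEGED_EXITED = "reneged_exited"
OUTCOME_CENSORED = "censored"


# ---------------------------------------------------------------------------
# compilation of parameters to per-day arrays
# ---------------------------------------------------------------------------


class _CompiledService:
    """Per-day schedules and samplers for one service (internal)."""

    __slots__ = (
        "sid",
        "index",
        "lam",
        "cap",
        "los_scale",
        "los_sampler",
        "trans_breaks",
        "trans_dests",
        "trans_cums",
        "seg",
        "renege_threshold",
        "renege_hazard",
        "renege_dests",
        "renege_cum",
    )

    def __init__(self, sp, index: int, ids: list[str], start: date, horizon: int, lam_col):
        self.sid = sp.service_id
        self.index = index
        self.lam = lam_col  # (H,) external arrival rate per day
        idx = {s: j for j, s in enumerate(ids)}
        n = len(ids)

        # capacity schedule
        if sp.capacity_factors:
            self.cap = np.array(
                [sp.capacity_on(start + timedelta(days=t)) for t in range(horizon)]
            )
        else:
            cap0 = sp.capacity if math.isinf(sp.capacity) else max(0, round(sp.capacity))
            self.cap = np.full(horizon, float(cap0))

        # LOS scale schedule
        if sp.los_factors:
            self.los_scale = np.array(
                [sp.los_scale_on(start + timedelta(days=t)) for t in range(horizon)]
            )
        else:
            self.los_scale = np.ones(horizon)
        self.los_sampler = sp.los.sample_continuous

        # piecewise-constant transition rows
        bounds = {0, horizon}
        for ff in sp.flow_factors:
            for d in ((ff.start - start).days, (ff.end - start).days):
                if 0 < d < horizon:
                    bounds.add(d)
        breaks = sorted(bounds)
        self.trans_breaks = breaks
        self.trans_dests, self.trans_cums = [], []
        for b in breaks[:-1]:
            row = sp.transition_row_on(start + timedelta(days=b))
            dests = np.array([n if d == EXIT else idx[d] for d in row], dtype=np.int64)
            probs = np.array(list(row.values()))
            self.trans_dests.append(dests)
            self.trans_cums.append(np.cumsum(probs))
        self.seg = 0

        # reneging
        if sp.renege is not None:
            self.renege_threshold = sp.renege.threshold_days
            self.renege_hazard = sp.renege.hazard
            dmap = sp.renege.destinations
            self.renege_dests = np.array(
                [n if d == EXIT else idx[d] for d in dmap], dtype=np.int64
            )
            self.renege_cum = np.cumsum(np.array(list(dmap.values())))
        else:
            self.renege_threshold = None
            self.renege_hazard = 0.0
            self.renege_dests = None
            self.renege_cum = None

    def row_at(self, day: int):
        while self.seg + 1 < len(self.trans_breaks) - 1 and day >= self.trans_breaks[self.seg + 1]:
            self.seg += 1
        return self.trans_dests[self.seg], self.trans_cums[self.seg]


# ---------------------------------------------------------------------------
# state and results
# ---------------------------------------------------------------------------


@dataclass
class SimState:
    """Mutable simulation state: day clock, queues, in-service buckets,
    occupancy and cumulative flow counters (all per service)."""

    day: int
    queues: list[deque]  # of (pid, join_day)
    in_service: list[dict]  # completion_day -> list of pids
    occupancy: np.ndarray  # int, per service
    counters: dict[str, np.ndarray]  # per-service cumulative counts
    next_pid: int = 0


@dataclass
class ResultSeries:
    """Weekly output series of a single replication."""

    services: list[str]
    start_date: date
    horizon_days: int
    warmup_weeks: int
    seed: int
    queue_size: np.ndarray  # (S, W) end-of-week waiting count
    occupancy: np.ndarray  # (S, W) end-of-week in-service count
    renege_from: np.ndarray  # (S, W) reneges out of each queue per week
    renege_to: np.ndarray  # (S, W) renege escalations into each queue per week
    counters: dict[str, np.ndarray]
    final_in_service: np.ndarray = field(default=None)
    final_in_queue: np.ndarray = field(default=None)

    @property
    def n_weeks(self) -> int:
        return self.queue_size.shape[1]

    def measure(self, name: str) -> np.ndarray:
        if name not in MEASURES:
            raise KeyError(f"unknown measure {name!r}; expected one of {MEASURES}")
        return getattr(self, name)

    def to_frame(self, include_warmup: bool = True) -> pd.DataFrame:
        rows = []
        w0 = 0 if include_warmup else self.warmup_weeks
        for m in MEASURES:
            arr = self.measure(m)
            for i, sid in enumerate(self.services):
                for w in range(w0, self.n_weeks):
                    rows.append((sid, w, m, arr[i, w]))
        return pd.DataFrame(rows, columns=["service", "week", "measure", "value"])


@dataclass
class ExperimentSummary:
    """Mean and 2.5/97.5% quantile weekly series over replications."""

    services: list[str]
    start_date: date
    horizon_days: int
    warmup_weeks: int
    n_replications: int
    seeds: list[int]
    measures: dict[str, dict[str, np.ndarray]]  # measure -> stat -> (S, W)

    @property
    def n_weeks(self) -> int:
        return next(iter(self.measures.values()))["mean"].shape[1]

    def series(self, measure: str, stat: str = "mean") -> np.ndarray:
        return self.measures[measure][stat]

    def week_of(self, when: date) -> int:
        w = (when - self.start_date).days // 7
        if not 0 <= w < self.n_weeks:
            raise ValueError(f"{when} outside the simulated horizon")
        return w

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, stats in self.measures.items():
            for stat, arr in stats.items():
                for i, sid in enumerate(self.services):
                    for w in range(arr.shape[1]):
                        rows.append((sid, w, m, stat, arr[i, w]))
        return pd.DataFrame(rows, columns=["service", "week", "measure", "stat", "value"])


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------


class Simulation:
    """One replication of the daily-step flow model.

    Parameters
    ----------
    params
        Validated :class:`~careflow.params.ModelParameters`.
    start_date, horizon_days
        Calendar anchor and run length; windowed scenario modifiers on
        ``params`` are resolved against ``start_date``.
    seed
        Seeds the replication's generator; identical seeds give identical
        runs.
    demand
        Optional ``(horizon_days, n_services)`` array of external arrival
        rates per day, e.g. from a scenario demand profile.  Defaults to the
        constant base rates in ``params``.
    trace
        Record a patient-level event log (one record per queue spell /
        service episode) -- used by the capacity-constrained synthetic-data
        mode.
    audit
        Assert capacity and FIFO invariants after every step.
    warm_start
        Pre-fill each service to its steady-state occupancy (traffic
        equations x mean stay, truncated at capacity) with residual stays,
        instead of starting from an empty system.
    """

    def __init__(
        self,
        params: ModelParameters,
        *,
        start_date: date,
        horizon_days: int,
        seed: int,
        demand: np.ndarray | None = None,
        trace: bool = False,
        audit: bool = False,
        warm_start: bool = False,
    ):
        params.validate()
        if horizon_days <= 0:
            raise ValueError("horizon_days must be positive")
        self.params = params
        self.ids = params.service_ids
        self.n = len(self.ids)
        self.start_date = start_date
        self.horizon = int(horizon_days)
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.audit = audit
        self.trace = trace
        self._trace_records: list = []
        self._waiting: dict = {}  # pid -> (service_idx, join_day)
        self._in_ep: dict = {}  # pid -> (service_idx, referral_day, start_day)

        if demand is None:
            base = np.array([params.services[s].arrival_rate for s in self.ids])
            demand = np.broadcast_to(base, (self.horizon, self.n))
        demand = np.asarray(demand, dtype=float)
        if demand.shape != (self.horizon, self.n):
            raise ValueError(
                f"demand must have shape {(self.horizon, self.n)}, got {demand.shape}"
            )
        if (demand < 0).any():
            raise ValueError("arrival rates must be >= 0")

        self.compiled = [
            _CompiledService(params.services[s], i, self.ids, start_date, self.horizon, demand[:, i])
            for i, s in enumerate(self.ids)
        ]
        # all external arrival counts drawn up front, one call
        self._arrivals = self.rng.poisson(demand)

        counters = {k: np.zeros(self.n, dtype=np.int64) for k in _COUNTER_KEYS}
        self.state = SimState(
            day=0,
            queues=[deque() for _ in range(self.n)],
            in_service=[{} for _ in range(self.n)],
            occupancy=np.zeros(self.n, dtype=np.int64),
            counters=counters,
        )

        n_weeks = math.ceil(self.horizon / 7)
        self._weekly = {m: np.zeros((self.n, n_weeks), dtype=np.int64) for m in MEASURES}

        if warm_start:
            self._warm_start()

    # -- setup -------------------------------------------------------------

    def _warm_start(self) -> None:
        lam_eff = self.params.effective_arrival_rates()
        st = self.state
        for cs in self.compiled:
            sp = self.params.services[cs.sid]
            target = lam_eff[cs.sid] * sp.los.mean_days()
            cap = cs.cap[0]
            k = int(min(target, cap)) if not math.isinf(cap) else int(target)
            if k <= 0:
                continue
            stays = cs.los_sampler(self.rng, k) * cs.los_scale[0]
            # residual stay: uniform over the sampled total stay
            remaining = np.maximum(1, np.rint(stays * self.rng.random(k))).astype(np.int64)
            for rem in remaining:
                pid = st.next_pid
                st.next_pid += 1
                st.in_service[cs.index].setdefault(int(rem), []).append(pid)
                if self.trace:
                    self._in_ep[pid] = (cs.index, 0, 0)
            st.occupancy[cs.index] += k
            st.counters["initial"][cs.index] += k

    # -- sampling helpers --------------------------------------------------

    def _sample_dests(self, dests: np.ndarray, cum: np.ndarray, k: int) -> np.ndarray:
        u = self.rng.random(k)
        return dests[np.searchsorted(cum, u, side="right")]

    # -- one day -----------------------------------------------------------

    def step(self) -> SimState:
        """Advance the state by one day, resolving the five phases in order."""
        st = self.state
        t = st.day
        if t >= self.horizon:
            raise RuntimeError("simulation horizon already reached")
        week = t // 7
        counts = st.counters

        # (1) external arrivals
        arr_today = self._arrivals[t]
        for cs in self.compiled:
            k = int(arr_today[cs.index])
            if k:
                q = st.queues[cs.index]
                for _ in range(k):
                    pid = st.next_pid
                    st.next_pid += 1
                    q.append((pid, t))
                    if self.trace:
                        self._waiting[pid] = (cs.index, t)
                counts["external"][cs.index] += k

        # (2) completions and transitions
        for cs in self.compiled:
            bucket = st.in_service[cs.index].pop(t, None)
            if not bucket:
                continue
            k = len(bucket)
            st.occupancy[cs.index] -= k
            counts["completions"][cs.index] += k
            dests_arr, cum = cs.row_at(t)
            chosen = self._sample_dests(dests_arr, cum, k)
            for pid, d in zip(bucket, chosen):
                if d == self.n:  # exit
                    counts["exits"][cs.index] += 1
                    if self.trace:
                        s, ref, start = self._in_ep.pop(pid)
                        self._trace_records.append(
                            (pid, s, ref, start, t, OUTCOME_DISCHARGED)
                        )
                else:
                    counts["transfers_out"][cs.index] += 1
                    counts["transfers_in"][d] += 1
                    st.queues[d].append((pid, t))
                    if self.trace:
                        s, ref, start = self._in_ep.pop(pid)
                        self._trace_records.append(
                            (pid, s, ref, start, t, OUTCOME_TRANSFERRED)
                        )
                        self._waiting[pid] = (d, t)

        # (3) admissions from queue heads
        for cs in self.compiled:
            q = st.queues[cs.index]
            if not q:
                continue
            cap = cs.cap[t]
            free = len(q) if math.isinf(cap) else int(cap) - int(st.occupancy[cs.index])
            k = min(free, len(q))
            if k <= 0:
                continue
            stays = cs.los_sampler(self.rng, k) * cs.los_scale[t]
            stay_days = np.maximum(1, np.rint(stays)).astype(np.int64)
            bucket_map = st.in_service[cs.index]
            for los in stay_days:
                pid, join = q.popleft()
                bucket_map.setdefault(t + int(los), []).append(pid)
                if self.trace:
                    self._waiting.pop(pid)
                    self._in_ep[pid] = (cs.index, join, t)
            st.occupancy[cs.index] += k
            counts["admissions"][cs.index] += k

        # (4) reneging
        for cs in self.compiled:
            if cs.renege_threshold is None:
                continue
            q = st.queues[cs.index]
            if not q or t - q[0][1] <= cs.renege_threshold:
                continue
            eligible = []
            while q and t - q[0][1] > cs.renege_threshold:
                eligible.append(q.popleft())
            if cs.renege_hazard >= 1.0:
                renegers = eligible
            else:
                u = self.rng.random(len(eligible))
                renegers = []
                survivors = []
                for entry, ui in zip(eligible, u):
                    (renegers if ui < cs.renege_hazard else survivors).append(entry)
                q.extendleft(reversed(survivors))
            if not renegers:
                continue
            counts["reneges_from"][cs.index] += len(renegers)
            self._weekly["renege_from"][cs.index, week] += len(renegers)
            chosen = self._sample_dests(cs.renege_dests, cs.renege_cum, len(renegers))
            for (pid, join), d in zip(renegers, chosen):
                if d == self.n:
                    counts["renege_exits"][cs.index] += 1
                    if self.trace:
                        self._waiting.pop(pid)
                        self._trace_records.append(
                            (pid, cs.index, join, None, t, OUTCOME_RENEGED_EXITED)
                        )
                else:
                    counts["renege_escalations"][cs.index] += 1
                    counts["reneges_in"][d] += 1
                    self._weekly["renege_to"][d, week] += 1
                    st.queues[d].append((pid, t))
                    if self.trace:
                        self._waiting.pop(pid)
                        self._trace_records.append(
                            (pid, cs.index, join, None, t, OUTCOME_RENEGED_ESCALATED)
                        )
                        self._waiting[pid] = (d, t)

        # (5) bookkeeping
        if t % 7 == 6 or t == self.horizon - 1:
            for i in range(self.n):
                self._weekly["queue_size"][i, week] = len(st.queues[i])
                self._weekly["occupancy"][i, week] = st.occupancy[i]

        if self.audit:
            self._assert_invariants(t)

        st.day = t + 1
        return st

    def _assert_invariants(self, t: int) -> None:
        st = self.state
        for cs in self.compiled:
            cap = cs.cap[t]
            if not math.isinf(cap):
                assert st.occupancy[cs.index] <= cap, (
                    f"day {t}: occupancy {st.occupancy[cs.index]} exceeds "
                    f"capacity {cap} at {cs.sid}"
                )
            q = st.queues[cs.index]
            joins = [j for _, j in q]
            assert all(a <= b for a, b in zip(joins, joins[1:])), (
                f"day {t}: FIFO order violated in queue at {cs.sid}"
            )

    # -- full run ----------------------------------------------------------

    def run(self, warmup_weeks: int = 0) -> ResultSeries:
        while self.state.day < self.horizon:
            self.step()
        st = self.state
        return ResultSeries(
            services=list(self.ids),
            start_date=self.start_date,
            horizon_days=self.horizon,
            warmup_weeks=int(warmup_weeks),
            seed=self.seed,
            queue_size=self._weekly["queue_size"].copy(),
            occupancy=self._weekly["occupancy"].copy(),
            renege_from=self._weekly["renege_from"].copy(),
            renege_to=self._weekly["renege_to"].copy(),
            counters={k: v.copy() for k, v in st.counters.items()},
            final_in_service=st.occupancy.copy(),
            final_in_queue=np.array([len(q) for q in st.queues], dtype=np.int64),
        )

    def event_log(self) -> pd.DataFrame:
        """Traced event log as a tidy table (requires ``trace=True``).

        Open episodes and unresolved queue spells at the horizon are emitted
        as censored records (missing end / start dates).
        """
        if not self.trace:
            raise RuntimeError("simulation was not run with trace=True")
        records = list(self._trace_records)
        for pid, (s, join) in self._waiting.items():
            records.append((pid, s, join, None, None, OUTCOME_CENSORED))
        for pid, (s, ref, start) in self._in_ep.items():
            records.append((pid, s, ref, start, None, OUTCOME_CENSORED))
        records.sort(key=lambda r: (r[0], r[2], r[3] if r[3] is not None else r[2]))
        origin = pd.Timestamp(self.start_date)

        def _dt(day):
            return origin + pd.Timedelta(days=int(day)) if day is not None else pd.NaT

        from .services import SERVICE_LEVELS

        rows = [
            {
                "patient_id": f"P{pid:07d}",
                "service_id": self.ids[s],
                "level": SERVICE_LEVELS.get(self.ids[s], 0),
                "referral_date": _dt(ref),
                "start_date": _dt(start),
                "end_date": _dt(end),
                "outcome": outcome,
            }
            for pid, s, ref, start, end, outcome in records
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "service_id",
                "level",
                "referral_date",
                "start_date",
                "end_date",
                "outcome",
            ],
        )


def run_replication(
    params: ModelParameters,
    *,
    start_date: date,
    horizon_days: int,
    seed: int,
    demand: np.ndarray | None = None,
    warmup_weeks: int = 0,
    audit: bool = False,
    warm_start: bool = False,
) -> ResultSeries:
    """Run one seeded replication and return its weekly series."""
    sim = Simulation(
        params,
        start_date=start_date,
        horizon_days=horizon_days,
        seed=seed,
        demand=demand,
        audit=audit,
        warm_start=warm_start,
    )
    return sim.run(warmup_weeks=warmup_weeks)


def replication_seeds(base_seed: int, n_replications: int) -> list[int]:
    """Deterministic per-replication seeds derived from a base seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n_replications)
    return [int(s) & 0x7FFFFFFF for s in state]


def run_experiment(
    params: ModelParameters,
    *,
    start_date: date,
    horizon_days: int,
    n_replications: int,
    base_seed: int,
    demand: np.ndarray | None = None,
    warmup_weeks: int = 0,
    warm_start: bool = False,
    keep_replications: bool = False,
) -> ExperimentSummary | tuple[ExperimentSummary, list[ResultSeries]]:
    """Run ``n_replications`` seeded replications and summarise them.

    The summary holds, for every measure/service/week, the mean and the
    empirical 2.5% and 97.5% quantiles (linear interpolation) across
    replications.
    """
    if n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    seeds = replication_seeds(base_seed, n_replications)
    reps = [
        run_replication(
            params,
            start_date=start_date,
            horizon_days=horizon_days,
            seed=s,
            demand=demand,
            warmup_weeks=warmup_weeks,
            warm_start=warm_start,
        )
        for s in seeds
    ]
    measures: dict[str, dict[str, np.ndarray]] = {}
    for m in MEASURES:
        stack = np.stack([r.measure(m) for r in reps])  # (R, S, W)
        measures[m] = {
            "mean": stack.mean(axis=0),
            "q2.5": np.quantile(stack, 0.025, axis=0),
            "q97.5": np.quantile(stack, 0.975, axis=0),
        }
    summary = ExperimentSummary(
        services=params.service_ids,
        start_date=start_date,
        horizon_days=horizon_days,
        warmup_weeks=warmup_weeks,
        n_replications=n_replications,
        seeds=seeds,
        measures=measures,
    )
    if keep_replications:
        return summary, reps
    return summary


# ---------------------------------------------------------------------------
# conservation audit
# ---------------------------------------------------------------------------


@dataclass
class BalanceReport:
    """Result of the patient-conservation audit."""

    ok: bool
    failures: list[str]
    totals: dict[str, int]

    def raise_on_imbalance(self) -> None:
        if not self.ok:
            raise AssertionError("conservation audit failed:\n" + "\n".join(self.failures))


def conservation_audit(result: ResultSeries) -> BalanceReport:
    """Check the flow-balance identities of a finished replication.

    Every patient seeded or arriving externally must, at the end of the run,
    be in a service, in a queue, exited after treatment, or reneged out of
    the pathway; internal moves (transfers, renege escalations) must balance
    pairwise; per-service queue and occupancy ledgers must close exactly.
    """
    c = result.counters
    failures: list[str] = []
    svc = result.services

    for i, sid in enumerate(svc):
        queue_in = c["external"][i] + c["transfers_in"][i] + c["reneges_in"][i]
        queue_out = c["admissions"][i] + c["reneges_from"][i]
        if queue_in - queue_out != result.final_in_queue[i]:
            failures.append(
                f"{sid}: queue ledger off by "
                f"{queue_in - queue_out - result.final_in_queue[i]}"
            )
        if c["admissions"][i] + c["initial"][i] - c["completions"][i] != result.final_in_service[i]:
            failures.append(f"{sid}: occupancy ledger does not close")
        if c["completions"][i] != c["transfers_out"][i] + c["exits"][i]:
            failures.append(f"{sid}: completions != transfers_out + exits")
        if c["reneges_from"][i] != c["renege_exits"][i] + c["renege_escalations"][i]:
            failures.append(f"{sid}: renege split does not sum")

    if c["transfers_in"].sum() != c["transfers_out"].sum():
        failures.append("system: transfers in != transfers out")
    if c["reneges_in"].sum() != c["renege_escalations"].sum():
        failures.append("system: renege escalations do not balance")

    inflow = int(c["initial"].sum() + c["external"].sum())
    outflow = int(
        result.final_in_service.sum()
        + result.final_in_queue.sum()
        + c["exits"].sum()
        + c["renege_exits"].sum()
    )
    if inflow != outflow:
        failures.append(f"system: {inflow} patients in vs {outflow} accounted for")

    totals = {
        "patients_in": inflow,
        "patients_accounted": outflow,
        "treated_exits": int(c["exits"].sum()),
        "renege_exits": int(c["renege_exits"].sum()),
    }
    return BalanceReport(ok=not failures, failures=failures, totals=totals)
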