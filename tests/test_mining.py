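import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from careflow.los import LosDistribution
from careflow.mining import (
    attendance_shares,
    build_pathway_graph,
    cohort_summary,
    estimate_parameters,
    reconstruct_pathways,
    referral_window_share,
)
from careflow.severity import (
    SEVERITY_METHODS_TEXT,
    SEVERITY_TABLE2_FOOTNOTES,
    classify_severity,
)
from careflow.synthetic import ACTIVITY_COLUMNS, SyntheticCohortSpec, generate_event_log

from conftest import two_service_params

ORIGIN = pd.Timestamp("2019-04-01")


def _record(pid, sid, level, ref, start=None, end=None, outcome="discharged"):
    return {
        "patient_id": pid,
        "service_id": sid,
        "level": level,
        "referral_date": ORIGIN + pd.Timedelta(days=ref),
        "start_date": ORIGIN + pd.Timedelta(days=start if start is not None else ref),
        "end_date": ORIGIN + pd.Timedelta(days=end) if end is not None else pd.NaT,
        "outcome": outcome,
    }


def _frame(rows):
    return pd.DataFrame(rows, columns=ACTIVITY_COLUMNS)


# ---------------------------------------------------------------------------
# pathway reconstruction
# ---------------------------------------------------------------------------


def test_single_record_gives_single_step_sequence():
    table = _frame([_record("P1", "L2_GP_high", 2, ref=0, end=3)])
    seqs = reconstruct_pathways(table)
    assert len(seqs) == 1
    assert seqs[0].services() == ["L2_GP_high"]


def test_out_of_order_rows_are_returned_date_sorted():
    rows = [
        _record("P1", "L3_IAPT_therapy", 3, ref=20, end=30, outcome="discharged"),
        _record("P1", "L2_GP_high", 2, ref=0, end=5, outcome="transferred"),
        _record("P1", "L3_IAPT_assessment", 3, ref=5, end=10, outcome="transferred"),
    ]
    seqs = reconstruct_pathways(_frame(rows))
    assert seqs[0].services() == ["L2_GP_high", "L3_IAPT_assessment", "L3_IAPT_therapy"]


def test_reconstruction_inverts_generation():
    spec = SyntheticCohortSpec(start=date(2019, 4, 1), end=date(2019, 10, 1), seed=17)
    log = generate_event_log(spec)
    shuffled = log.sample(frac=1.0, random_state=0).reset_index(drop=True)
    seqs = {s.patient_id: s.services() for s in reconstruct_pathways(shuffled)}
    expected = {pid: list(g["service_id"]) for pid, g in log.groupby("patient_id")}
    assert seqs == expected


def test_overlapping_episodes_truncated_with_warning():
    rows = [
        _record("P1", "L2_GP_high", 2, ref=0, end=10, outcome="transferred"),
        _record("P1", "L3_IAPT_therapy", 3, ref=5, start=5, end=12),
    ]
    with pytest.warns(UserWarning, match="truncated 1 overlapping"):
        seqs = reconstruct_pathways(_frame(rows))
    first = seqs[0].steps[0]
    assert first.end_date == ORIGIN + pd.Timedelta(days=5)


# ---------------------------------------------------------------------------
# pathway graph
# ---------------------------------------------------------------------------


def test_repeated_identical_pathways_give_one_full_frequency_edge():
    rows = []
    for pid in ("P1", "P2"):
        rows.append(_record(pid, "L2_GP_high", 2, ref=0, end=3, outcome="transferred"))
        rows.append(_record(pid, "L3_IAPT_therapy", 3, ref=3, start=3, end=9, outcome="censored"))
    graph = build_pathway_graph(reconstruct_pathways(_frame(rows)))
    edges = graph.edge_frame()
    assert len(edges) == 1
    edge = edges.iloc[0]
    assert (edge["source"], edge["target"]) == ("L2_GP_high", "L3_IAPT_therapy")
    assert edge["count"] == 2
    assert edge["rel_freq_pct"] == pytest.approx(100.0)


def test_branching_pathways_split_edge_frequency():
    rows = [
        _record("P1", "L2_GP_high", 2, ref=0, end=3, outcome="transferred"),
        _record("P1", "L3_IAPT_therapy", 3, ref=3, start=3, end=9, outcome="censored"),
        _record("P2", "L2_GP_high", 2, ref=0, end=3, outcome="transferred"),
        _record("P2", "L4_MHP_triage", 4, ref=3, start=3, end=9, outcome="censored"),
    ]
    graph = build_pathway_graph(reconstruct_pathways(_frame(rows)))
    edges = graph.edge_frame().set_index("target")
    assert edges.loc["L3_IAPT_therapy", "rel_freq_pct"] == pytest.approx(50.0)
    assert edges.loc["L4_MHP_triage", "rel_freq_pct"] == pytest.approx(50.0)


def test_graph_totals_are_conserved():
    spec = SyntheticCohortSpec(start=date(2019, 4, 1), end=date(2019, 12, 1), seed=23)
    log = generate_event_log(spec)
    graph = build_pathway_graph(reconstruct_pathways(log))
    nodes = graph.node_frame()
    assert nodes.loc[nodes["service"] != "exit", "count"].sum() == len(log)
    assert graph.edge_frame()["count"].sum() == graph.total_transitions
    live = nodes[nodes["service"] != "exit"]
    assert live["rel_freq_pct"].sum() == pytest.approx(100.0)


def test_graph_edge_frequencies_recover_ground_truth_within_3se():
    p = 0.3
    params = two_service_params(p_forward=p, arrival_rate=30.0)
    spec = SyntheticCohortSpec(
        start=date(2019, 4, 1), end=date(2021, 4, 1), ground_truth=params, seed=29
    )
    log = generate_event_log(spec)
    graph = build_pathway_graph(reconstruct_pathways(log))
    g = graph.graph
    n = g["L2_GP_high"]["L3_IAPT_therapy"]["count"] + g["L2_GP_high"]["exit"]["count"]
    observed = g["L2_GP_high"]["L3_IAPT_therapy"]["count"] / n
    assert abs(observed - p) < 3 * math.sqrt(p * (1 - p) / n)
    # capacity-free log with immediate transitions: zero median gap
    assert g["L2_GP_high"]["L3_IAPT_therapy"]["median_gap_weeks"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


def test_single_exit_pathway_estimates_certain_exit():
    table = _frame([_record("P1", "L2_GP_high", 2, ref=0, end=3)])
    est = estimate_parameters(reconstruct_pathways(table))
    assert est.transition_probs.loc["L2_GP_high", "exit"] == 1.0


def test_mean_los_from_two_episodes():
    # stays of 2 and 4 weeks -> mean 3 weeks, empirical support {14, 28} days
    rows = [
        _record("P1", "L3_IAPT_therapy", 3, ref=0, end=14),
        _record("P2", "L3_IAPT_therapy", 3, ref=0, end=28),
    ]
    est = estimate_parameters(reconstruct_pathways(_frame(rows)))
    assert est.mean_los_weeks("L3_IAPT_therapy") == pytest.approx(3.0)
    assert sorted(est.los_days["L3_IAPT_therapy"]) == [14.0, 28.0]


def test_arrival_definition_counts_reentry_after_exit():
    rows = [
        _record("P1", "L2_GP_high", 2, ref=0, end=3, outcome="discharged"),
        _record("P1", "L2_GP_high", 2, ref=50, end=53, outcome="transferred"),
        _record("P1", "L3_IAPT_therapy", 3, ref=53, start=53, end=60, outcome="censored"),
    ]
    est = estimate_parameters(reconstruct_pathways(_frame(rows)), horizon_days=100)
    # two external arrivals at GP (initial + post-discharge re-entry); the
    # therapy episode continues the second pathway, so it is not an arrival
    assert est.arrival_rate["L2_GP_high"] == pytest.approx(2 / 100)
    assert est.arrival_rate["L3_IAPT_therapy"] == 0.0


def test_renege_outcomes_feed_renege_rate_not_transitions():
    rows = [
        _record("P1", "L2_GP_high", 2, ref=0, end=3, outcome="transferred"),
        {
            "patient_id": "P1",
            "service_id": "L3_IAPT_therapy",
            "level": 3,
            "referral_date": ORIGIN + pd.Timedelta(days=3),
            "start_date": pd.NaT,
            "end_date": ORIGIN + pd.Timedelta(days=17),  # reneged after a 14-day wait
            "outcome": "reneged_exited",
        },
    ]
    est = estimate_parameters(reconstruct_pathways(_frame(rows)), horizon_days=100)
    assert est.renege_rate["L3_IAPT_therapy"] == pytest.approx(1 / 2.0)  # 1 per 2 wait-weeks
    assert est.transition_probs.loc["L3_IAPT_therapy", "exit"] == 1.0
    assert "L3_IAPT_therapy" in est.flagged_services


def test_estimates_recover_ground_truth_on_moderate_log():
    spec = SyntheticCohortSpec(start=date(2019, 4, 1), end=date(2020, 4, 1), seed=31)
    log = generate_event_log(spec)
    est = estimate_parameters(reconstruct_pathways(log), horizon_days=spec.horizon_days)
    gt = spec.ground_truth
    for sid in ("L2_GP_high", "L2_GP_low"):
        true = gt.services[sid].arrival_rate
        assert est.arrival_rate[sid] == pytest.approx(true, rel=0.1)
    row = est.transition_probs.loc["L2_GP_high"]
    for dest, p in gt.services["L2_GP_high"].transitions.items():
        assert row[dest] == pytest.approx(p, abs=0.05)


def test_estimates_round_trip_into_simulator_schema(tmp_path):
    spec = SyntheticCohortSpec(start=date(2019, 4, 1), end=date(2019, 10, 1), seed=37)
    log = generate_event_log(spec)
    est = estimate_parameters(reconstruct_pathways(log))
    params = est.to_model_parameters()
    path = tmp_path / "mined.yaml"
    params.to_yaml(path)
    from careflow.params import ModelParameters

    back = ModelParameters.from_yaml(path)
    assert back.service_ids == params.service_ids
    for sid in params.service_ids:
        assert sum(back.services[sid].transitions.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# severity
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "flags,config,expected",
    [
        ({"depression"}, SEVERITY_METHODS_TEXT, "severe"),
        ({"adhd"}, SEVERITY_METHODS_TEXT, "moderate"),
        (set(), SEVERITY_METHODS_TEXT, "mild"),
        ({"depression"}, SEVERITY_TABLE2_FOOTNOTES, "moderate"),
        ({"adhd"}, SEVERITY_TABLE2_FOOTNOTES, "severe"),
        ({"adhd", "depression"}, SEVERITY_METHODS_TEXT, "severe"),
    ],
)
def test_severity_classification(flags, config, expected):
    assert classify_severity(flags, config) == expected


def test_severity_is_order_independent_and_total():
    flags = ["adhd", "depression", "autism"]
    for config in (SEVERITY_METHODS_TEXT, SEVERITY_TABLE2_FOOTNOTES):
        assert classify_severity(flags, config) == classify_severity(reversed(flags), config)
    assert classify_severity({"unmapped_code"}, SEVERITY_METHODS_TEXT) == "mild"
    with pytest.raises(ValueError, match="unknown condition codes"):
        classify_severity({"unmapped_code"}, SEVERITY_METHODS_TEXT, strict=True)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


def test_cohort_summary_reproduces_sex_percentages():
    # 59,488 female + 36,671 male in one service -> 61.9% / 38.1%
    n_f, n_m = 59_488, 36_671
    pids = [f"P{i}" for i in range(n_f + n_m)]
    attributes = pd.DataFrame(
        {
            "patient_id": pids,
            "sex": ["female"] * n_f + ["male"] * n_m,
            "age_band": "40-59",
            "ethnicity": "white",
            "ses_quintile": 3,
            "condition_flags": "",
        }
    )
    activity = pd.DataFrame(
        {
            "patient_id": pids,
            "service_id": "L2_GP_high",
            "level": 2,
            "referral_date": ORIGIN,
            "start_date": ORIGIN,
            "end_date": ORIGIN + pd.Timedelta(days=1),
            "outcome": "discharged",
        }
    )
    summary = cohort_summary(attributes, activity)
    sex = summary[(summary["attribute"] == "sex")].set_index("category")
    assert sex.loc["female", "pct"] == 61.9
    assert sex.loc["male", "pct"] == 38.1
    n_row = summary[summary["attribute"] == "_patients"].iloc[0]
    assert n_row["count"] == n_f + n_m


def test_single_patient_summary_is_total():
    attributes = pd.DataFrame(
        {
            "patient_id": ["P1"],
            "sex": ["female"],
            "age_band": ["18-29"],
            "ethnicity": ["white"],
            "ses_quintile": [1],
            "condition_flags": ["depression"],
        }
    )
    activity = _frame([_record("P1", "L5_AWP_inpatient", 5, ref=0, end=5)])
    summary = cohort_summary(attributes, activity, severity_config=SEVERITY_METHODS_TEXT)
    assert (summary[summary["attribute"] != "_patients"]["pct"] == 100.0).all()
    sev = summary[summary["attribute"] == "severity"]
    assert list(sev["category"]) == ["severe"]


def test_attendance_shares_by_level():
    # 88 level-2/3 attendances of 100 -> 88.0%
    rows = []
    for i in range(88):
        rows.append(_record(f"P{i}", "L2_GP_high", 2, ref=0, end=1))
    for i in range(88, 100):
        rows.append(_record(f"P{i}", "L4_MHP_general", 4, ref=0, end=1))
    shares = attendance_shares(_frame(rows)).set_index("level")
    assert shares.loc[2, "pct"] == 88.0
    assert shares.loc[4, "pct"] == 12.0
    assert shares["attendances"].sum() == 100


def test_referral_window_share_uses_both_denominators():
    rows = [
        _record("P1", "L2_GP_high", 2, ref=0, end=1),
        _record("P1", "L2_GP_high", 2, ref=400, end=401),
        _record("P2", "L2_GP_high", 2, ref=400, end=401),
    ]
    out = referral_window_share(
        _frame(rows), ORIGIN + pd.Timedelta(days=366), ORIGIN + pd.Timedelta(days=731)
    )
    assert out["patients_in_window"] == 2
    assert out["pct_of_patients"] == 100.0
    assert out["pct_of_attendances"] == pytest.approx(66.7)
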