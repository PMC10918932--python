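from datetime import date

import numpy as np
import pandas as pd
import pytest

from careflow.los import LosDistribution
from careflow.params import default_parameters
from careflow.scenarios import (
    DemandSegment,
    FlowChange,
    InterventionSpec,
    LosChange,
    ScenarioSpec,
    apply_intervention,
    build_demand_profile,
    compare_scenarios,
    load_preset,
    preset_scenarios,
    run_scenario,
    scale_relative,
)
from careflow.simulate import run_experiment

from conftest import single_service_params

START = date(2019, 4, 1)
H = 1827  # through 1 April 2024


def _profile(scenario, params=None):
    params = params or default_parameters()
    return (
        params,
        build_demand_profile(params, scenario, start_date=START, horizon_days=H),
    )


def _day(d: date) -> int:
    return (d - START).days


# ---------------------------------------------------------------------------
# demand profiles
# ---------------------------------------------------------------------------


def test_no_segments_is_identity():
    params, lam = _profile(ScenarioSpec(name="null"))
    base = np.array([params.services[s].arrival_rate for s in params.service_ids])
    assert np.array_equal(lam, np.tile(base, (H, 1)))


def test_doubling_window_reverts_to_base():
    scenario = ScenarioSpec(
        name="x",
        demand_segments=[
            DemandSegment(("L2_GP_high",), date(2021, 4, 1), date(2021, 10, 1), 2.0)
        ],
    )
    params, lam = _profile(scenario)
    j = params.service_ids.index("L2_GP_high")
    base = params.services["L2_GP_high"].arrival_rate
    assert lam[_day(date(2021, 5, 1)), j] == pytest.approx(2 * base)
    assert lam[_day(date(2021, 11, 1)), j] == pytest.approx(base)


def test_assessment_trajectory_steps_through_three_phases():
    # weekly base 10 -> 8 from April 2021, 12.5 from April 2022, 10 from Oct 2022
    params = default_parameters()
    params.services["L3_IAPT_assessment"].arrival_rate = 10.0 / 7.0
    scenario = load_preset("baseline_a")
    lam = build_demand_profile(params, scenario, start_date=START, horizon_days=H)
    j = params.service_ids.index("L3_IAPT_assessment")
    weekly = lambda d: 7 * lam[_day(d), j]  # noqa: E731
    assert weekly(date(2021, 6, 1)) == pytest.approx(8.0)
    assert weekly(date(2022, 6, 1)) == pytest.approx(12.5)
    assert weekly(date(2022, 11, 1)) == pytest.approx(10.0)


def test_unknown_service_in_segment_rejected():
    scenario = ScenarioSpec(
        name="x",
        demand_segments=[DemandSegment(("L9_none",), date(2021, 4, 1), date(2021, 5, 1), 2.0)],
    )
    with pytest.raises(ValueError, match="unknown service"):
        _profile(scenario)


def test_demand_profile_is_linear_in_base_rates():
    scenario = load_preset("baseline_b")
    params = default_parameters()
    _, lam1 = _profile(scenario, params)
    scaled = params.copy()
    for sp in scaled.services.values():
        sp.arrival_rate *= 3.0
    lam3 = build_demand_profile(scaled, scenario, start_date=START, horizon_days=H)
    np.testing.assert_allclose(lam3, 3.0 * lam1)


# ---------------------------------------------------------------------------
# interventions
# ---------------------------------------------------------------------------


def test_empty_intervention_changes_nothing():
    params = default_parameters()
    out = apply_intervention(params, InterventionSpec())
    assert out.to_dict() == params.to_dict()
    for sp in out.services.values():
        assert not (sp.capacity_factors or sp.los_factors or sp.flow_factors)
    out2 = apply_intervention(params, None)
    assert out2.to_dict() == params.to_dict()


def test_specialist_los_target_seventy_weeks():
    # baseline mean stay of 78 weeks cut to an absolute 70-week target
    params = default_parameters()
    sp = params.services["L4_MHP_specialist"]
    assert sp.los.mean_weeks() == pytest.approx(78.0)
    out = apply_intervention(params, load_preset("intervention_b").intervention)
    mod = out.services["L4_MHP_specialist"]
    assert mod.effective_los_mean_weeks(date(2021, 6, 1)) == pytest.approx(70.0)
    assert mod.effective_los_mean_weeks(date(2023, 6, 1)) == pytest.approx(78.0)


def test_flow_change_renormalises_row_inside_window():
    params = default_parameters()
    out = apply_intervention(
        params,
        InterventionSpec(
            flow=[
                FlowChange(
                    "L4_MHP_specialist",
                    "L4_MHP_general",
                    1.3,
                    date(2021, 4, 1),
                    date(2022, 10, 1),
                )
            ]
        ),
    )
    sp = out.services["L4_MHP_specialist"]
    inside = sp.transition_row_on(date(2021, 6, 1))
    outside = sp.transition_row_on(date(2023, 6, 1))
    assert outside == sp.transitions
    assert inside["L4_MHP_general"] == pytest.approx(sp.transitions["L4_MHP_general"] * 1.3)
    assert sum(inside.values()) == pytest.approx(1.0)
    untouched = [k for k in sp.transitions if k != "L4_MHP_general"]
    ratios = {k: inside[k] / sp.transitions[k] for k in untouched}
    assert len(set(round(v, 12) for v in ratios.values())) == 1  # proportional


def test_flow_factor_pushing_edge_above_one_rejected():
    params = default_parameters()
    with pytest.raises(ValueError, match="> 1"):
        apply_intervention(
            params,
            InterventionSpec(
                flow=[
                    FlowChange(
                        "L5_AWP_inpatient",
                        "L4_MHP_specialist",
                        4.0,
                        date(2021, 4, 1),
                        date(2022, 4, 1),
                    )
                ]
            ),
        )


def test_preset_multipliers_and_factors():
    presets = preset_scenarios()
    # trajectory A doubles GP demand in May 2021
    assert presets["baseline_a"].multiplier("L2_GP_high", date(2021, 5, 1)) == 2.0
    assert presets["baseline_a"].multiplier("L2_GP_high", date(2021, 11, 1)) == 1.0
    # trajectory B: primary care +20% in fiscal year 2021/22
    assert presets["baseline_b"].multiplier("L2_GP_low", date(2021, 8, 1)) == pytest.approx(1.20)
    assert presets["baseline_b"].multiplier("L4_MHP_general", date(2022, 8, 1)) == pytest.approx(1.14)
    # mitigation A: +30% level-2 capacity
    cap = presets["intervention_a"].intervention.capacity
    assert any(
        c.factor == pytest.approx(1.30) and "L2_GP_high" in c.services for c in cap
    )
    # the narrower variant touches only IAPT therapy stays
    narrow = presets["intervention_a_table1"].intervention.los
    assert [c.services for c in narrow] == [("L3_IAPT_therapy",)]


def test_scenario_yaml_round_trip(tmp_path):
    scenario = load_preset("intervention_b")
    path = tmp_path / "s.yaml"
    scenario.to_yaml(path)
    back = ScenarioSpec.from_yaml(path)
    assert back.to_dict() == scenario.to_dict()


def test_los_change_requires_exactly_one_mode():
    with pytest.raises(ValueError):
        LosChange(("L2_GP_high",), date(2021, 4, 1), date(2021, 5, 1))
    with pytest.raises(ValueError):
        LosChange(
            ("L2_GP_high",), date(2021, 4, 1), date(2021, 5, 1), factor=0.8, target_mean_weeks=10
        )


# ---------------------------------------------------------------------------
# relative scaling and comparison tables
# ---------------------------------------------------------------------------


def _toy_summary(n_reps=5, horizon=210, lam=4.0, seed=1):
    params = single_service_params(
        lam, LosDistribution.lognormal_from_mean(5.0, 0.5), capacity=12
    )
    return run_experiment(
        params,
        start_date=START,
        horizon_days=horizon,
        n_replications=n_reps,
        base_seed=seed,
    )


def test_scale_relative_constant_series_becomes_unity():
    summary = _toy_summary()
    ref = date(2019, 8, 1)
    scaled, flagged = scale_relative(summary, ref)
    w = summary.week_of(ref)
    occ = scaled.series("occupancy", "mean")[0]
    assert occ[w] == pytest.approx(1.0)
    # inverse check: scaled x reference value reproduces the original
    restored = occ * summary.series("occupancy", "mean")[0, w]
    np.testing.assert_allclose(restored, summary.series("occupancy", "mean")[0])
    # no reneging is configured, so those series are zero at the reference
    # week and cannot be scaled: flagged and omitted (NaN)
    assert ("renege_from", "L2_GP_high") in flagged
    assert np.isnan(scaled.series("renege_from", "mean")).all()


def test_compare_identical_summaries_is_zero():
    summary = _toy_summary()
    table = compare_scenarios(summary, summary)
    changed = table.dropna(subset=["max_pct_change"])
    assert (changed["max_pct_change"] == 0).all()
    assert (changed.dropna(subset=["mean_pct_change"])["mean_pct_change"] == 0).all()


def test_compare_scenarios_reports_mean_shift():
    # baseline window mean 100, intervention mean 44 -> -56%
    base = _toy_summary()
    inter = _toy_summary()
    base.measures["occupancy"]["mean"][:] = 100.0
    inter.measures["occupancy"]["mean"][:] = 44.0
    table = compare_scenarios(base, inter).set_index(["service", "measure"])
    row = table.loc[("L2_GP_high", "occupancy")]
    assert row["mean_pct_change"] == pytest.approx(-56.0)
    assert row["max_pct_change"] == pytest.approx(-56.0)


def test_compare_requires_matching_horizons():
    with pytest.raises(ValueError, match="horizon"):
        compare_scenarios(_toy_summary(horizon=210), _toy_summary(horizon=140))


def test_comparison_matches_bruteforce_recomputation_from_replications():
    params = single_service_params(
        5.0,
        LosDistribution.lognormal_from_mean(6.0, 0.6),
        capacity=20,
    )
    kwargs = dict(start_date=START, horizon_days=280, n_replications=8, warmup_weeks=4)
    base, base_reps = run_experiment(params, base_seed=5, keep_replications=True, **kwargs)
    boosted = params.copy()
    for sp in boosted.services.values():
        sp.arrival_rate *= 1.4
    inter, inter_reps = run_experiment(boosted, base_seed=5, keep_replications=True, **kwargs)
    table = compare_scenarios(base, inter).set_index(["service", "measure"])

    def stat(reps, measure, agg):
        stack = np.stack([r.measure(measure) for r in reps]).mean(axis=0)[0, 4:]
        return agg(stack)

    for measure in ("occupancy", "queue_size"):
        b_max, i_max = stat(base_reps, measure, np.max), stat(inter_reps, measure, np.max)
        b_mean, i_mean = stat(base_reps, measure, np.mean), stat(inter_reps, measure, np.mean)
        row = table.loc[("L2_GP_high", measure)]
        if b_max > 0:
            assert row["max_pct_change"] == pytest.approx(100 * (i_max - b_max) / b_max)
        if b_mean > 0:
            assert row["mean_pct_change"] == pytest.approx(100 * (i_mean - b_mean) / b_mean)


def test_demand_surge_and_capacity_relief_move_queues_the_right_way():
    params = single_service_params(
        3.0, LosDistribution.lognormal_from_mean(5.0, 0.5), capacity=16
    )
    kwargs = dict(start_date=START, horizon_days=420, n_replications=35, base_seed=21)
    base = run_experiment(params, **kwargs)

    surged = params.copy()
    surged.services["L2_GP_high"].arrival_rate *= 2.0
    surge = run_experiment(surged, **kwargs)
    assert (
        surge.series("queue_size", "mean")[0, 10:].mean()
        >= base.series("queue_size", "mean")[0, 10:].mean()
    )

    relieved = surged.copy()
    relieved.services["L2_GP_high"].capacity *= 1.5
    relief = run_experiment(relieved, **kwargs)
    assert (
        relief.series("queue_size", "mean")[0, 10:].mean()
        <= surge.series("queue_size", "mean")[0, 10:].mean()
    )


def test_run_scenario_wires_demand_and_intervention_together():
    params = default_parameters()
    summary = run_scenario(
        params,
        load_preset("baseline_a"),
        start_date=START,
        horizon_days=400,
        n_replications=2,
        base_seed=2,
        warmup_weeks=4,
    )
    assert summary.n_replications == 2
    assert summary.services == params.service_ids
    assert summary.n_weeks == (400 + 6) // 7
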