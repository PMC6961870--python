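"""Scenario engine: simulated CSF profiles and the four testing policies."""

import numpy as np
import pandas as pd
import pytest

from csftriage import (
    CSF_FEATURES,
    ScenarioConfig,
    derive_simulated_csf_profiles,
    outcomes_to_frame,
    pcc_cutoff_sweep,
    run_all_scenarios,
    run_scenario,
)
from csftriage.cohort import Cohort

from oracles import scenario_a_oracle


def test_profiles_are_group_medians(default_pipeline):
    cohort = default_pipeline["cohort"]
    pos, neg = default_pipeline["profiles"]
    assert pos.polarity == "positive" and neg.polarity == "negative"
    for analyte in CSF_FEATURES:
        ad_vals = sorted(
            cohort.data.loc[cohort.data["diagnosis"] == "AD", analyte].dropna()
        )
        ctl_vals = sorted(
            cohort.data.loc[cohort.data["diagnosis"] == "CONTROL", analyte].dropna()
        )

        def median(vals):  # independent sort-and-pick oracle
            n = len(vals)
            return vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2

        assert getattr(pos, analyte) == pytest.approx(median(ad_vals))
        assert getattr(neg, analyte) == pytest.approx(median(ctl_vals))


def test_five_value_median_fixture(default_pipeline):
    cohort = default_pipeline["cohort"]
    df = cohort.data.copy()
    ad_rows = df.index[df["diagnosis"] == "AD"][:5]
    df.loc[df["diagnosis"] == "AD", "ab42"] = np.nan
    df.loc[ad_rows, "ab42"] = [560.0, 520.0, 580.0, 500.0, 540.0]
    fixture = Cohort(df, catalog=cohort.catalog, corrected=True)
    pos, _ = derive_simulated_csf_profiles(fixture)
    assert pos.ab42 == 540.0


def test_scenario_flags_match_straight_line_oracle(default_pipeline):
    cohort = default_pipeline["cohort"]
    outcome_lists = run_all_scenarios(
        cohort,
        default_pipeline["dsi_nocsf"],
        default_pipeline["dsi_csf"],
        default_pipeline["pcc_nocsf"],
        default_pipeline["pcc_csf"],
        default_pipeline["profiles"],
    )
    # scenario A against the flow-chart transcription, patient by patient
    a_by_id = {o.patient_id: o for o in outcome_lists["A"]}
    d_by_id = {o.patient_id: o for o in outcome_lists["D"]}
    for o in outcome_lists["A"]:
        sim_pos = o.pcc_sim_positive
        sim_neg = o.pcc_sim_negative
        if o.decision_group == 1:
            assert sim_pos is None and sim_neg is None
            continue
        actual = d_by_id[o.patient_id].pcc_final  # same with-CSF evaluation
        tested, trigger, group, diagnosed = scenario_a_oracle(
            o.pcc_step1, sim_pos, sim_neg, actual, 0.80
        )
        assert (o.csf_tested, o.trigger, o.decision_group, o.diagnosed) == (
            tested, trigger, group, diagnosed,
        )


def test_partition_nesting_and_structural_invariants(default_pipeline):
    cohort = default_pipeline["cohort"]
    outcome_lists = run_all_scenarios(
        cohort,
        default_pipeline["dsi_nocsf"],
        default_pipeline["dsi_csf"],
        default_pipeline["pcc_nocsf"],
        default_pipeline["pcc_csf"],
        default_pipeline["profiles"],
    )
    a = outcome_lists["A"]
    groups = {g: {o.patient_id for o in a if o.decision_group == g} for g in (1, 2, 3, 4)}
    # decision groups partition the cohort
    assert sum(len(v) for v in groups.values()) == cohort.n
    tested_a = {o.patient_id for o in a if o.csf_tested}
    diagnosed_a = {o.patient_id for o in a if o.diagnosed}
    assert tested_a == groups[3] | groups[4]
    assert diagnosed_a == groups[1] | groups[3]
    # every tested patient has a simulation trigger; triggers partition them
    for o in a:
        if o.csf_tested:
            assert o.trigger in {"positive_only", "negative_only", "both"}
        elif o.decision_group == 2:
            assert o.trigger == "none"
        else:
            assert o.trigger == "n/a"
    # diagnosed under B  =>  directly diagnosed (group 1) under A
    diagnosed_b = {o.patient_id for o in outcome_lists["B"] if o.diagnosed}
    assert diagnosed_b == groups[1]
    assert all(not o.csf_tested for o in outcome_lists["B"])
    assert all(o.csf_tested for o in outcome_lists["D"])
    # scenario C tests exactly the AUC-positive patients
    X = cohort.data[list(cohort.feature_names)]
    dsi_ad = default_pipeline["dsi_nocsf"].evaluate(X)["dsi_AD"].to_numpy()
    auc_pos = set(cohort.data["patient_id"][dsi_ad > 0.6])
    assert {o.patient_id for o in outcome_lists["C"] if o.csf_tested} == auc_pos


def test_missing_actual_csf_for_tested_patient_is_an_error(default_pipeline):
    cohort = default_pipeline["cohort"]
    outcomes = run_all_scenarios(
        cohort,
        default_pipeline["dsi_nocsf"],
        default_pipeline["dsi_csf"],
        default_pipeline["pcc_nocsf"],
        default_pipeline["pcc_csf"],
        default_pipeline["profiles"],
    )["A"]
    tested_id = next(o.patient_id for o in outcomes if o.csf_tested)
    df = cohort.data.copy()
    df.loc[df["patient_id"] == tested_id, "ab42"] = np.nan
    broken = Cohort(df, catalog=cohort.catalog, corrected=True)
    with pytest.raises(ValueError, match=f"{tested_id}.*ab42"):
        run_scenario(
            broken,
            default_pipeline["dsi_nocsf"],
            default_pipeline["dsi_csf"],
            default_pipeline["pcc_nocsf"],
            default_pipeline["pcc_csf"],
            default_pipeline["profiles"],
            ScenarioConfig("A"),
        )


def test_cutoff_sweep_shares_and_monotonicity(default_pipeline):
    cohort = default_pipeline["cohort"]
    sweep = pcc_cutoff_sweep(
        cohort,
        default_pipeline["dsi_nocsf"],
        default_pipeline["dsi_csf"],
        default_pipeline["pcc_nocsf"],
        default_pipeline["pcc_csf"],
        default_pipeline["profiles"],
        cutoffs=np.arange(0.5, 1.0001, 0.05),
    )
    b = sweep[sweep["scenario"] == "B"]
    d = sweep[sweep["scenario"] == "D"]
    assert (b["share_tested"] == 0).all()
    assert (d["share_tested"] == 1).all()
    for s in "ABCD":
        sub = sweep[sweep["scenario"] == s].sort_values("cutoff")
        assert (np.diff(sub["share_diagnosed"]) <= 1e-12).all()
    # share diagnosed under A dominates B at every cutoff
    a = sweep[sweep["scenario"] == "A"].sort_values("cutoff")
    b = b.sort_values("cutoff")
    assert (a["share_diagnosed"].to_numpy() >= b["share_diagnosed"].to_numpy() - 1e-12).all()


def test_outcomes_frame_round_trips_fields(default_pipeline):
    cohort = default_pipeline["cohort"]
    outcomes = run_scenario(
        cohort,
        default_pipeline["dsi_nocsf"],
        default_pipeline["dsi_csf"],
        default_pipeline["pcc_nocsf"],
        default_pipeline["pcc_csf"],
        default_pipeline["profiles"],
        ScenarioConfig("A"),
    )
    frame = outcomes_to_frame(outcomes)
    assert len(frame) == cohort.n
    assert (frame["diagnosed"] == (frame["pcc_final"] >= 0.80)).all()
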