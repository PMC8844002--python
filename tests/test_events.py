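"""Event-log parsing, coder agreement, treatment flagging, eligibility."""

import io

import pandas as pd
import pytest

from pathshade.events import (
    apply_eligibility,
    coder_agreement,
    flag_treatment_decisions,
    parse_events,
)
from pathshade.simulate import SimulationConfig, simulate_study


def _event_log(participant="P001", coder="C1", n_trials=13, sun_pattern=None, sep=","):
    """Synthetic coded-event CSV: an initial sun_presence event, then one
    decision + end_of_trial pair per trial, at one-minute spacing."""
    sun_pattern = sun_pattern or {}
    lines = ["participant_id,coder_id,event_code,time,x_m,y_m,state,chose_A".replace(",", sep)]
    t0 = pd.Timestamp("2019-07-15T10:00:00+08:00")

    def add(code, minutes, state="", chose=""):
        t = (t0 + pd.Timedelta(minutes=minutes)).isoformat()
        lines.append(sep.join([participant, coder, code, t, "1.0", "2.0", state, chose]))

    add("sun_presence", 0, state="full_sun")
    for trial in range(1, n_trials + 1):
        base = trial * 2
        if trial in sun_pattern:
            add("sun_presence", base - 1, state=sun_pattern[trial])
        add("decision", base, chose=str(trial % 2))
        add("end_of_trial", base + 1)
    return "\n".join(lines) + "\n"


class TestParseEvents:
    def test_well_formed_log_round_trips(self):
        events, errors = parse_events(io.StringIO(_event_log()))
        assert len(errors) == 0
        assert (events["event_code"] == "decision").sum() == 13
        assert (events["event_code"] == "end_of_trial").sum() == 13
        assert events["time"].is_monotonic_increasing

    def test_semicolon_dialect_and_bom_tolerated(self):
        text = "﻿" + _event_log(sep=";")
        events, errors = parse_events(io.StringIO(text))
        assert len(errors) == 0
        assert (events["event_code"] == "decision").sum() == 13

    def test_decision_without_label_is_a_row_error(self):
        bad = _event_log().replace(
            "P001,C1,decision,2019-07-15T10:02:00+08:00,1.0,2.0,,1",
            "P001,C1,decision,2019-07-15T10:02:00+08:00,1.0,2.0,,",
        )
        events, errors = parse_events(io.StringIO(bad))
        assert len(errors) == 1
        assert "chose_A" in errors.iloc[0]["reason"]
        assert (events["event_code"] == "decision").sum() == 12

    def test_unknown_code_and_bad_timestamp_reported_with_lines(self):
        log = _event_log()
        log += "P001,C1,teleport,2019-07-15T11:00:00+08:00,0,0,,\n"
        log += "P001,C1,water_intake,not-a-time,0,0,,\n"
        events, errors = parse_events(io.StringIO(log))
        assert len(errors) == 2
        assert errors["line"].tolist() == [29, 30]
        reasons = " | ".join(errors["reason"])
        assert "unknown event code" in reasons and "timestamp" in reasons

    def test_out_of_order_timestamp_flagged(self):
        log = _event_log(n_trials=2)
        log += "P001,C1,water_intake,2019-07-15T09:00:00+08:00,0,0,,\n"
        events, errors = parse_events(io.StringIO(log))
        assert any("earlier than preceding" in r for r in errors["reason"])
        assert "water_intake" not in set(events["event_code"])


class TestCoderAgreement:
    def test_identical_logs_fully_agree(self):
        e1, _ = parse_events(io.StringIO(_event_log(coder="C1")))
        e2, _ = parse_events(io.StringIO(_event_log(coder="C2")))
        report = coder_agreement(e1, e2)
        assert report.n_disagreements == 0
        assert len(report.unmatched) == 0
        assert len(report.agreements) == 27  # 13 decisions + 13 ends + 1 sun event

    @pytest.mark.parametrize("shift_s, flagged", [(5, False), (6, True)])
    def test_time_difference_boundary_is_strictly_more_than_five_seconds(self, shift_s, flagged):
        e1, _ = parse_events(io.StringIO(_event_log()))
        e2, _ = parse_events(io.StringIO(_event_log(coder="C2")))
        e2 = e2.copy()
        first_decision = e2.index[e2["event_code"] == "decision"][0]
        e2.loc[first_decision, "time"] += pd.Timedelta(seconds=shift_s)
        report = coder_agreement(e1, e2)
        assert (report.n_disagreements > 0) == flagged

    def test_decision_label_disagreement_flagged(self):
        e1, _ = parse_events(io.StringIO(_event_log()))
        e2, _ = parse_events(io.StringIO(_event_log(coder="C2")))
        e2 = e2.copy()
        first_decision = e2.index[e2["event_code"] == "decision"][0]
        e2.loc[first_decision, "chose_A"] = not e2.loc[first_decision, "chose_A"]
        report = coder_agreement(e1, e2)
        assert report.n_disagreements == 1
        assert "decision label" in report.disagreements.iloc[0]["reason"]

    def test_extra_events_reported_unmatched(self):
        e1, _ = parse_events(io.StringIO(_event_log(n_trials=13)))
        e2, _ = parse_events(io.StringIO(_event_log(coder="C2", n_trials=12)))
        report = coder_agreement(e1, e2)
        assert len(report.unmatched) == 2  # one decision + one end_of_trial

    def test_different_participants_rejected(self):
        e1, _ = parse_events(io.StringIO(_event_log(participant="P001")))
        e2, _ = parse_events(io.StringIO(_event_log(participant="P002")))
        with pytest.raises(ValueError, match="different participants"):
            coder_agreement(e1, e2)


class TestFlagTreatmentDecisions:
    def test_latest_prior_sun_state_attached(self):
        log = _event_log(sun_pattern={3: "no_sun", 5: "cloudy_sun"})
        events, _ = parse_events(io.StringIO(log))
        decisions = flag_treatment_decisions(events)
        assert len(decisions) == 13
        by_trial = decisions.set_index("trial_id")
        assert by_trial.loc[1, "sun_state"] == "full_sun" and by_trial.loc[1, "treatment"]
        assert by_trial.loc[3, "sun_state"] == "no_sun" and not by_trial.loc[3, "treatment"]
        assert by_trial.loc[4, "sun_state"] == "no_sun"
        assert by_trial.loc[5, "sun_state"] == "cloudy_sun" and by_trial.loc[5, "treatment"]

    def test_state_toggle_just_before_decision_wins(self):
        # full_sun -> no_sun one second before the decision: not treatment
        log = _event_log(n_trials=1)
        extra = "P001,C1,sun_presence,2019-07-15T10:01:59+08:00,1.0,2.0,no_sun,\n"
        lines = log.splitlines()
        lines.insert(2, extra.strip())
        events, errors = parse_events(io.StringIO("\n".join(lines)))
        assert len(errors) == 0
        decisions = flag_treatment_decisions(events)
        assert not decisions.iloc[0]["treatment"]

    def test_decision_before_any_sun_state_is_an_error(self):
        log = _event_log(n_trials=1)
        # drop the initial sun_presence line
        lines = [l for l in log.splitlines() if "sun_presence" not in l]
        events, _ = parse_events(io.StringIO("\n".join(lines)))
        with pytest.raises(ValueError, match="P001"):
            flag_treatment_decisions(events)


class TestApplyEligibility:
    @pytest.fixture()
    def cohort(self):
        frame, _ = simulate_study(SimulationConfig(seed=77))
        return frame

    def test_full_sun_cohort_yields_552_treatment_decisions(self, cohort):
        cohort = cohort.copy()
        # everyone passes the test trial (chooses the dominating option B)
        cohort.loc[cohort["trial_id"] == 13, "chose_A"] = 0
        analysis, statuses = apply_eligibility(cohort, None, test_trial_id=13)
        assert len(analysis) == 46 * 12
        assert statuses["eligible"].all()
        assert statuses["n_treatment_decisions"].sum() == 552

    def test_test_trial_failures_excluded(self, cohort):
        cohort = cohort.copy()
        # participant P001 chooses the dominated (longer, sunnier) option A
        mask = (cohort["participant_id"] == "P001") & (cohort["trial_id"] == 13)
        cohort.loc[mask, "chose_A"] = 1
        others = (cohort["trial_id"] == 13) & (cohort["participant_id"] != "P001")
        cohort.loc[others, "chose_A"] = 0
        analysis, statuses = apply_eligibility(cohort, None, test_trial_id=13)
        row = statuses.set_index("participant_id").loc["P001"]
        assert not row["eligible"]
        assert row["exclusion_reason"] == "failed_test_trial"
        assert "P001" not in set(analysis["participant_id"])
        assert len(analysis) == 45 * 12

    def test_no_sun_participant_retained_with_zero_treatment_decisions(self, cohort):
        cohort = cohort.copy()
        cohort["treatment"] = ~(cohort["participant_id"] == "P002")
        cohort.loc[cohort["trial_id"] == 13, "chose_A"] = 0
        analysis, statuses = apply_eligibility(cohort, None, test_trial_id=13)
        row = statuses.set_index("participant_id").loc["P002"]
        assert row["eligible"]
        assert row["n_treatment_decisions"] == 0
        assert "P002" not in set(analysis["participant_id"])

    def test_filtering_is_idempotent(self, cohort):
        analysis1, statuses1 = apply_eligibility(cohort, None, test_trial_id=13)
        analysis2, statuses2 = apply_eligibility(analysis1, statuses1, test_trial_id=13)
        pd.testing.assert_frame_equal(
            analysis1.reset_index(drop=True), analysis2.reset_index(drop=True)
        )

    def test_totals_reconcile_and_reasons_machine_readable(self, cohort):
        statuses = pd.DataFrame({
            "participant_id": sorted(cohort["participant_id"].unique()),
            "eligible": True,
            "exclusion_reason": [None] * 46,
        })
        statuses.loc[0, "exclusion_reason"] = "missing_data_or_rain"
        statuses.loc[1, "exclusion_reason"] = "navigation_intervention"
        cohort = cohort.copy()
        cohort.loc[cohort["trial_id"] == 13, "chose_A"] = 0
        analysis, out = apply_eligibility(cohort, statuses, test_trial_id=13)
        assert (~out["eligible"]).sum() == 2
        assert out["eligible"].sum() + (~out["eligible"]).sum() == 46
        assert analysis["participant_id"].nunique() == 44
        with pytest.raises(ValueError, match="unknown exclusion"):
            bad = statuses.copy()
            bad.loc[2, "exclusion_reason"] = "bad_vibes"
            apply_eligibility(cohort, bad, test_trial_id=13)
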