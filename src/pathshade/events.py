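"""Coded-event ingestion, cross-coder agreement, and eligibility filtering.

The raw observational record of each participant is a chronological log of
coded events (decisions, trial ends, sun-presence changes, sun-exposure
changes, water intakes).  This module parses and validates those logs,
compares two coders' versions of the same log, attaches the prevailing
sun-presence state to every decision ("treatment" decisions are those made
with the sun out), and applies the eligibility rules that produce the final
analysis table: ineligible participants removed, the designated test trial
dropped, and participants who chose the dominated option on the test trial
excluded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .choice import PathComposition, TrialRecord, classify_trial, ChosenStrategy

__all__ = [
    "EVENT_CODES",
    "SUN_PRESENCE_STATES",
    "SUN_EXPOSURE_STATES",
    "DEFAULT_SUN_PRESENT_STATES",
    "parse_events",
    "coder_agreement",
    "flag_treatment_decisions",
    "apply_eligibility",
]

EVENT_CODES = {"decision", "end_of_trial", "sun_presence", "sun_exposure", "water_intake"}
SUN_PRESENCE_STATES = {"full_sun", "cloudy_sun", "no_sun"}
SUN_EXPOSURE_STATES = {"no_shade", "tree_shade", "building_shade"}
#: Sun-presence states counted as "sun present": both full and cloudy sun
#: cast visible shadows, so both default to treatment.
DEFAULT_SUN_PRESENT_STATES = frozenset({"full_sun", "cloudy_sun"})

_EVENT_COLUMNS = ["participant_id", "coder_id", "event_code", "time", "x_m", "y_m", "state", "chose_A"]

EXCLUSION_REASONS = {
    "missing_data_or_rain",
    "failed_test_trial",
    "navigation_intervention",
    "self_corrected_path",
}


def _read_delimited(source) -> pd.DataFrame:
    """Read a comma- or semicolon-delimited event file, tolerating a UTF-8 BOM."""
    if isinstance(source, (str, Path)):
        raw = Path(source).read_text(encoding="utf-8-sig")
    else:
        raw = source.read()
    first = raw.splitlines()[0] if raw else ""
    sep = ";" if first.count(";") > first.count(",") else ","
    return pd.read_csv(io.StringIO(raw), sep=sep, dtype=str, keep_default_na=False)


def parse_events(source) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse and validate a coded-event file.

    Returns ``(events, errors)``: validated events sorted chronologically per
    participant, and a row-level error report (line number, reason) for
    malformed rows, which are excluded but never silently dropped.
    """
    df = _read_delimited(source)
    missing_cols = set(_EVENT_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"event file is missing required columns: {sorted(missing_cols)}")
    for col in _EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = ""

    errors: list[dict] = []
    rows: list[dict] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # 1-based with header
        code = row.event_code
        problems = []
        if code not in EVENT_CODES:
            problems.append(f"unknown event code {code!r}")
        ts = pd.NaT
        try:
            ts = pd.Timestamp(row.time)
            if ts.tzinfo is None:
                problems.append("timestamp lacks a timezone")
        except (ValueError, TypeError):
            problems.append(f"unparseable timestamp {row.time!r}")
        state = row.state or None
        if code == "sun_presence" and state not in SUN_PRESENCE_STATES:
            problems.append(f"sun_presence event needs a state in {sorted(SUN_PRESENCE_STATES)}")
        if code == "sun_exposure" and state not in SUN_EXPOSURE_STATES:
            problems.append(f"sun_exposure event needs a state in {sorted(SUN_EXPOSURE_STATES)}")
        if code in {"decision", "end_of_trial", "water_intake"} and state:
            problems.append(f"{code} event must not carry a state")
        chose = row.chose_A
        if code == "decision":
            if chose not in {"0", "1", "True", "False", "true", "false"}:
                problems.append("decision event needs a boolean chose_A")
        elif chose:
            problems.append(f"{code} event must not carry chose_A")
        if problems:
            errors.append({"line": line_no, "participant_id": row.participant_id,
                           "reason": "; ".join(problems)})
            continue
        rows.append({
            "participant_id": row.participant_id,
            "coder_id": row.coder_id,
            "event_code": code,
            "time": ts,
            "x_m": float(row.x_m) if row.x_m else np.nan,
            "y_m": float(row.y_m) if row.y_m else np.nan,
            "state": state,
            "chose_A": bool(int({"True": 1, "true": 1, "False": 0, "false": 0}.get(chose, chose)))
            if code == "decision" else None,
            "line": line_no,
        })
    events = pd.DataFrame(rows, columns=_EVENT_COLUMNS + ["line"])

    # unordered timestamps are row-level errors, flagged against the later row
    ordered = []
    for pid, group in events.groupby("participant_id", sort=False):
        last = None
        for _, ev in group.iterrows():
            if last is not None and ev["time"] < last:
                errors.append({"line": int(ev["line"]), "participant_id": pid,
                               "reason": "timestamp earlier than preceding event"})
                continue
            last = ev["time"]
            ordered.append(ev)
    events = pd.DataFrame(ordered, columns=_EVENT_COLUMNS + ["line"])
    events = events.sort_values(["participant_id", "time"], kind="stable").reset_index(drop=True)
    return events, pd.DataFrame(errors, columns=["line", "participant_id", "reason"])


@dataclass(frozen=True)
class AgreementReport:
    """Cross-coder comparison of one participant's event log."""

    agreements: pd.DataFrame
    disagreements: pd.DataFrame
    unmatched: pd.DataFrame

    @property
    def n_disagreements(self) -> int:
        return len(self.disagreements)


def coder_agreement(
    events_coder1: pd.DataFrame,
    events_coder2: pd.DataFrame,
    time_tolerance_s: float = 5.0,
) -> AgreementReport:
    """Compare two coders' logs of the same participant.

    Events are paired by event code in chronological sequence.  A pair is a
    disagreement iff the decision labels differ, the sun-presence states
    differ, or the times differ by strictly more than ``time_tolerance_s``
    seconds (5 s exactly still agrees).  Leftover events on either side are
    reported as unmatched.
    """
    p1 = set(events_coder1["participant_id"].unique())
    p2 = set(events_coder2["participant_id"].unique())
    if p1 != p2:
        raise ValueError(f"coder logs cover different participants: {sorted(p1)} vs {sorted(p2)}")

    agreements, disagreements, unmatched = [], [], []
    for code in sorted(EVENT_CODES):
        g1 = events_coder1[events_coder1["event_code"] == code].reset_index(drop=True)
        g2 = events_coder2[events_coder2["event_code"] == code].reset_index(drop=True)
        n = min(len(g1), len(g2))
        for i in range(n):
            a, b = g1.iloc[i], g2.iloc[i]
            reasons = []
            dt = abs((a["time"] - b["time"]).total_seconds())
            if dt > time_tolerance_s:
                reasons.append(f"time differs by {dt:.0f} s")
            if code == "decision" and a["chose_A"] != b["chose_A"]:
                reasons.append("decision label differs")
            if code == "sun_presence" and a["state"] != b["state"]:
                reasons.append("sun presence differs")
            entry = {
                "event_code": code, "index": i,
                "time_1": a["time"], "time_2": b["time"],
                "reason": "; ".join(reasons),
            }
            (disagreements if reasons else agreements).append(entry)
        for i in range(n, len(g1)):
            unmatched.append({"event_code": code, "index": i, "coder": 1, "time": g1.iloc[i]["time"]})
        for i in range(n, len(g2)):
            unmatched.append({"event_code": code, "index": i, "coder": 2, "time": g2.iloc[i]["time"]})
    cols = ["event_code", "index", "time_1", "time_2", "reason"]
    return AgreementReport(
        agreements=pd.DataFrame(agreements, columns=cols),
        disagreements=pd.DataFrame(disagreements, columns=cols),
        unmatched=pd.DataFrame(unmatched, columns=["event_code", "index", "coder", "time"]),
    )


def flag_treatment_decisions(
    events: pd.DataFrame,
    sun_present_states: frozenset[str] | set[str] = DEFAULT_SUN_PRESENT_STATES,
) -> pd.DataFrame:
    """Attach the prevailing sun-presence state to every decision event.

    The state in effect at a decision is that of the most recent prior
    sun-presence event of the same participant; a decision is a treatment
    decision iff that state is in ``sun_present_states``.  Decisions are
    numbered 1..n per participant in chronological order as ``trial_id``.
    """
    out = []
    for pid, group in events.sort_values("time", kind="stable").groupby("participant_id"):
        state = None
        trial = 0
        for _, ev in group.iterrows():
            if ev["event_code"] == "sun_presence":
                state = ev["state"]
            elif ev["event_code"] == "decision":
                trial += 1
                if state is None:
                    raise ValueError(
                        f"decision {trial} of participant {pid!r} occurs before any "
                        "sun_presence event; sun state unknown"
                    )
                out.append({
                    "participant_id": pid,
                    "trial_id": trial,
                    "time": ev["time"],
                    "chose_A": bool(ev["chose_A"]),
                    "sun_state": state,
                    "treatment": state in sun_present_states,
                })
    return pd.DataFrame(out, columns=["participant_id", "trial_id", "time", "chose_A", "sun_state", "treatment"])


def _chose_dominated_test_option(row: pd.Series) -> bool:
    """True if the participant picked the dominated option of a test trial."""
    trial = TrialRecord(
        participant_id=row["participant_id"],
        trial_id=int(row["trial_id"]),
        choice_set=int(row.get("choice_set", 1)),
        option_A=PathComposition(row["a_sun_A"], row["a_tree_A"], row["a_shade_A"]),
        option_B=PathComposition(row["a_sun_B"], row["a_tree_B"], row["a_shade_B"]),
        chose_A=bool(row["chose_A"]),
    )
    return classify_trial(trial, rho=1.0).chosen_strategy == ChosenStrategy.NON_OPTIMAL


def apply_eligibility(
    decisions: pd.DataFrame,
    statuses: pd.DataFrame | None,
    test_trial_id: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce the analysis table from a full decision table.

    * participants already marked ineligible in ``statuses`` are removed;
    * a participant choosing the dominated option of the designated test
      trial is marked ``failed_test_trial`` and removed;
    * the test trial itself is dropped from all analyses;
    * only treatment decisions remain in the returned analysis table, but
      participants with zero treatment decisions stay in the status table
      (eligible, ``n_treatment_decisions = 0``).

    Returns ``(analysis_table, statuses)``; the operation is idempotent.
    ``statuses`` may be None, in which case every participant starts eligible.
    """
    decisions = decisions.copy()
    if "treatment" not in decisions.columns:
        decisions["treatment"] = True
    participants = pd.Index(sorted(decisions["participant_id"].unique()), name="participant_id")
    if statuses is None or len(statuses) == 0:
        statuses = pd.DataFrame({
            "participant_id": participants,
            "eligible": True,
            "exclusion_reason": [None] * len(participants),
        })
    statuses = statuses.copy()
    unknown = set(statuses["exclusion_reason"].dropna()) - EXCLUSION_REASONS
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")

    # test-trial failures
    is_test = decisions["trial_id"] == test_trial_id
    comp_cols = {"a_sun_A", "a_tree_A", "a_shade_A", "a_sun_B", "a_tree_B", "a_shade_B"}
    if comp_cols <= set(decisions.columns):
        failed = {
            row["participant_id"]
            for _, row in decisions[is_test].iterrows()
            if _chose_dominated_test_option(row)
        }
    else:
        failed = set()
    newly_failed = statuses["participant_id"].isin(failed) & statuses["eligible"]
    statuses.loc[newly_failed, "eligible"] = False
    statuses.loc[newly_failed, "exclusion_reason"] = "failed_test_trial"
    statuses["eligible"] = statuses["exclusion_reason"].isna()

    eligible = set(statuses.loc[statuses["eligible"], "participant_id"])
    analysis = decisions[
        decisions["participant_id"].isin(eligible)
        & ~is_test
        & decisions["treatment"].astype(bool)
    ].reset_index(drop=True)

    n_treat = analysis.groupby("participant_id").size()
    statuses["n_treatment_decisions"] = (
        statuses["participant_id"].map(n_treat).fillna(0).astype(int)
    )
    return analysis, statuses
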