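"""Weekly coaching engine: model-driven advisor, file replay, and reporting.

The advisor wires the per-participant model pipeline to the coach: each week
it rebuilds the aligned dataset from the data observed so far, refits the
ridge model, ranks factor impacts, and selects the recommendation (generic
rotation while cold-starting). The same advisor runs in two places:

* inside :func:`bpcoach.synthetic_cohort.generate_cohort`, closing the loop
  during data generation, and
* in :func:`replay_run`, which replays the engine over previously written
  files (data streams + ground-truth file, the stand-in for the human
  participants when simulating check-ins) to produce the event logs.

Both paths consume identical recorded values and identically keyed RNG
streams, so they emit the same events.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coach import (
    DEFAULT_CATALOG,
    CheckIn,
    Recommendation,
    RecommendationEvent,
    aggregate_checkins,
    compose_weekly_message,
    select_recommendation,
)
from .core_types import (
    LIFESTYLE_FACTORS,
    QUESTIONNAIRE_FACTORS,
    WEARABLE_FACTORS,
    BPReading,
    BPSession,
    Slot,
    week_of_day,
)
from .io import add_week, session_means
from .outcomes_stats import (
    TransitionResult,
    change_table,
    cohort_flow,
    engagement_weekly,
    transition_table,
)
from .personal_model import (
    ColdStartError,
    build_dataset_arrays,
    fit_personal_model,
    rank_factor_impact,
)
from .safety_monitor import ActionKind, SafetyAction, SafetyState, process_session

N_WEARABLE = len(WEARABLE_FACTORS)


@dataclass
class EngineConfig:
    """Engine-side options: alignment window, cold-start threshold, model
    regularization, ranking repetitions, and the difficulty-based skip rule."""

    window: int = 1
    min_rows: int = 14
    ridge_alpha: float = 1.0
    perm_repeats: int = 20
    skip_rule: bool = True


def _pid_number(pid: str) -> int:
    digits = "".join(ch for ch in pid if ch.isdigit())
    return int(digits) if digits else abs(hash(pid)) % (2**31)


class ModelCoachAdvisor:
    """Selects and composes one recommendation per participant-week."""

    def __init__(self, engine_config: EngineConfig, seed: int,
                 catalog: Sequence[Recommendation] = DEFAULT_CATALOG):
        self.config = engine_config
        self.seed = seed
        self.catalog = catalog

    def rank(self, pid: str, week: int, recorded: np.ndarray,
             sessions: Sequence[Tuple[int, float, float]]):
        """Fit and rank on data observed through the given week; None while
        cold-starting."""
        data = build_dataset_arrays(pid, recorded, sessions, window=self.config.window)
        try:
            model = fit_personal_model(
                data, min_rows=self.config.min_rows, alpha=self.config.ridge_alpha
            )
        except ColdStartError:
            return None
        perm_seed = int(
            np.random.SeedSequence(
                [self.seed, _pid_number(pid), week, 4]
            ).generate_state(1)[0] % (2**31)
        )
        return rank_factor_impact(
            model, data, repeats=self.config.perm_repeats, seed=perm_seed
        )

    def deliver(self, truth, week: int, recorded: np.ndarray,
                sessions: Sequence[Tuple[int, float, float]],
                history) -> RecommendationEvent:
        pid = truth.participant_id
        ranking = self.rank(pid, week, recorded, sessions)
        rec = select_recommendation(
            ranking, history, week, catalog=self.catalog,
            skip_rule=self.config.skip_rule,
        )
        week_sess = [(s, d) for day, s, d in sessions if week_of_day(day) == week]
        prev_sess = [(s, d) for day, s, d in sessions if week_of_day(day) == week - 1]
        delivered = _dt.datetime.combine(
            truth.onboard_date + _dt.timedelta(days=7 * week - 1), _dt.time(18, 0)
        )
        return compose_weekly_message(
            pid, week, rec, week_sess, prev_sess,
            existing_events=[e for e, _ in history], delivered_at=delivered,
        )


# ---------------------------------------------------------------------------
# Replay over files
# ---------------------------------------------------------------------------


def _truths_from_frame(truth_df: pd.DataFrame):
    from .core_types import BPCategory
    from .synthetic_cohort import PatientTruth

    truths = []
    for _, row in truth_df.iterrows():
        wk = row.get("withdraw_week")
        truths.append(PatientTruth(
            participant_id=row["participant_id"],
            onboard_date=row["onboard_date"],
            baseline_category=BPCategory(row["baseline_category"]),
            baseline_sbp=float(row["baseline_sbp"]),
            baseline_dbp=float(row["baseline_dbp"]),
            coef={f: float(row[f"coef_{f}"]) for f in LIFESTYLE_FACTORS},
            noise_sd=float(row["noise_sd"]),
            med_flag=bool(row["med_flag"]),
            adherence_slope=float(row["adherence_slope"]),
            follow_intercept=float(row["follow_intercept"]),
            dropout_hazard=(0.0, 0.0),
            dominant_factor=(row["dominant_factor"] or None)
            if isinstance(row.get("dominant_factor"), str) else None,
            withdraw_week=None if pd.isna(wk) else int(wk),
        ))
    return truths


def _recorded_matrix(truth, life: pd.DataFrame, quest: pd.DataFrame,
                     n_days: int) -> np.ndarray:
    F = np.full((n_days, len(LIFESTYLE_FACTORS)), np.nan)
    for _, row in life.iterrows():
        r = (row["date"] - truth.onboard_date).days
        if 0 <= r < n_days:
            for j, f in enumerate(WEARABLE_FACTORS):
                if pd.notna(row[f]):
                    F[r, j] = float(row[f])
    for _, row in quest.iterrows():
        r = (row["date"] - truth.onboard_date).days
        if 0 <= r < n_days:
            for j, f in enumerate(QUESTIONNAIRE_FACTORS):
                if pd.notna(row[f]):
                    F[r, N_WEARABLE + j] = float(row[f])
    return F


@dataclass
class RunLogs:
    recommendations: List[RecommendationEvent]
    checkins: List[CheckIn]
    safety_actions: List[SafetyAction]

    def recommendations_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.recommendations:
            s = e.bp_summary
            rows.append({
                "participant_id": e.participant_id, "week": e.week,
                "rec_id": e.rec_id, "factor": e.factor,
                "delivered_at": e.delivered_at.isoformat() if e.delivered_at else "",
                "mean_sbp": None if s.mean_sbp is None else round(s.mean_sbp, 2),
                "mean_dbp": None if s.mean_dbp is None else round(s.mean_dbp, 2),
                "delta_sbp": None if s.delta_sbp is None else round(s.delta_sbp, 2),
                "delta_dbp": None if s.delta_dbp is None else round(s.delta_dbp, 2),
            })
        return pd.DataFrame(rows, columns=[
            "participant_id", "week", "rec_id", "factor", "delivered_at",
            "mean_sbp", "mean_dbp", "delta_sbp", "delta_dbp"])

    def checkins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"participant_id": c.participant_id, "week": c.week,
              "rec_id": c.rec_id, "followed": c.followed,
              "difficulty": c.difficulty} for c in self.checkins],
            columns=["participant_id", "week", "rec_id", "followed", "difficulty"])

    def safety_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"participant_id": a.participant_id,
              "timestamp": a.timestamp.isoformat(), "week": a.week,
              "kind": a.kind.value, "flag": a.flag.value}
             for a in self.safety_actions if a.kind is not ActionKind.NONE],
            columns=["participant_id", "timestamp", "week", "kind", "flag"])


def replay_run(
    seed: int,
    weeks: int,
    bp: pd.DataFrame,
    lifestyle: pd.DataFrame,
    questionnaire: pd.DataFrame,
    truth_df: pd.DataFrame,
    engine_config: Optional[EngineConfig] = None,
    behavior_step: float = 0.4,
) -> RunLogs:
    """Replay the weekly engine over written files, emitting the event logs.

    Deterministic given the seed: model fits and recommendation selection
    depend only on the files; check-in responses are drawn from the same
    participant/week-keyed RNG streams the generator uses.
    """
    from .synthetic_cohort import _CHECKIN, _rng, simulate_response

    engine_config = engine_config or EngineConfig()
    advisor = ModelCoachAdvisor(engine_config, seed)
    truths = _truths_from_frame(truth_df)
    sess_all = session_means(bp)
    n_days = weeks * 7

    events_all: List[RecommendationEvent] = []
    checkins_all: List[CheckIn] = []
    safety_all: List[SafetyAction] = []

    for idx, truth in enumerate(truths):
        pid = truth.participant_id
        life = lifestyle[lifestyle["participant_id"] == pid]
        quest = questionnaire[questionnaire["participant_id"] == pid]
        recorded = _recorded_matrix(truth, life, quest, n_days)
        psess = sess_all[sess_all["participant_id"] == pid].sort_values("timestamp")
        triples = [
            ((ts.date() - truth.onboard_date).days + 1, float(s), float(d))
            for ts, s, d in zip(psess["timestamp"], psess["mean_sbp"], psess["mean_dbp"])
        ]

        # safety pass over the chronological sessions
        state = SafetyState(participant_id=pid, onboarding_day=truth.onboard_date)
        for ts, s, d, slot in zip(psess["timestamp"], psess["mean_sbp"],
                                  psess["mean_dbp"], psess["slot"]):
            session = BPSession(
                participant_id=pid, timestamp=ts.to_pydatetime(),
                slot=Slot(slot),
                readings=(BPReading(float(s), float(d)),),
            )
            state, action = process_session(state, session)
            if action.kind is not ActionKind.NONE:
                safety_all.append(action)

        events: List[RecommendationEvent] = []
        history: List = []
        last_week = truth.withdraw_week if truth.withdraw_week else weeks
        for week in range(1, last_week + 1):
            if events and events[-1].week == week - 1:
                event = events[-1]
                rng_c = _rng(seed, idx, event.week, _CHECKIN)
                difficulty = int(rng_c.integers(1, 6))
                rec = next(r for r in advisor.catalog if r.rec_id == event.rec_id)
                checkin, _delta = simulate_response(
                    truth, rec, difficulty, rng_c, step=behavior_step
                )
                checkin = replace(checkin, week=event.week)
                checkins_all.append(checkin)
                history[-1] = (event, checkin)
            if truth.withdraw_week is not None and week >= truth.withdraw_week:
                break
            sessions_so_far = [t for t in triples if t[0] <= 7 * week]
            event = advisor.deliver(
                truth=truth, week=week, recorded=recorded[: 7 * week],
                sessions=sessions_so_far, history=history,
            )
            events.append(event)
            history.append((event, None))
        events_all.extend(events)

    return RunLogs(events_all, checkins_all, safety_all)


# ---------------------------------------------------------------------------
# Analysis over files
# ---------------------------------------------------------------------------


@dataclass
class OutcomeReport:
    """Cohort outcome tables and summaries for the configured anchors."""

    change_tables: Dict[int, pd.DataFrame]
    transitions: Dict[int, TransitionResult]
    engagement_weekly: pd.DataFrame
    engagement_summary: Dict[str, float]
    flow: Dict[str, float]
    checkin_summary: Optional[object] = None
    escalations: Optional[Tuple[int, int, float]] = None


def analyze_cohort(
    bp: pd.DataFrame,
    lifestyle: pd.DataFrame,
    questionnaire: pd.DataFrame,
    truth_df: pd.DataFrame,
    weeks: int,
    anchors: Sequence[int] = (12, 24),
    checkins: Optional[pd.DataFrame] = None,
    safety: Optional[pd.DataFrame] = None,
    contacted: Optional[int] = None,
    consented: Optional[int] = None,
) -> OutcomeReport:
    """Compute the full outcome report from files alone (replayable)."""
    onboard = dict(zip(truth_df["participant_id"], truth_df["onboard_date"]))
    sess = add_week(session_means(bp), onboard) if len(bp) else pd.DataFrame(
        columns=["participant_id", "week", "mean_sbp", "mean_dbp"])

    change_tables: Dict[int, pd.DataFrame] = {}
    transitions: Dict[int, TransitionResult] = {}
    for anchor in anchors:
        if anchor > weeks:
            continue
        change_tables[anchor] = change_table(sess, anchor)
        transitions[anchor] = transition_table(sess, anchor)

    last_active = {
        row["participant_id"]: (int(row["withdraw_week"])
                                if pd.notna(row.get("withdraw_week")) else weeks)
        for _, row in truth_df.iterrows()
    }
    life_w = add_week(lifestyle, onboard) if len(lifestyle) else pd.DataFrame(
        columns=["participant_id", "week"])
    quest_w = add_week(questionnaire, onboard) if len(questionnaire) else pd.DataFrame(
        columns=["participant_id", "week"])
    weekly, summary = engagement_weekly(
        sess if len(sess) else pd.DataFrame(columns=["participant_id", "week"]),
        life_w, quest_w, last_active, weeks,
    )

    withdraw = truth_df["withdraw_week"] if "withdraw_week" in truth_df else []
    flow = cohort_flow(
        onboarded=len(truth_df),
        withdraw_weeks=list(withdraw),
        boundary_week=min(anchors) if anchors else 12,
        final_week=weeks,
        contacted=contacted,
        consented=consented,
    )

    checkin_summary = None
    if checkins is not None and len(checkins):
        checkin_summary = aggregate_checkins([
            CheckIn(r["participant_id"], int(r["week"]), int(r["rec_id"]),
                    bool(r["followed"]), int(r["difficulty"]))
            for _, r in checkins.iterrows()
        ])

    escalations = None
    if safety is not None:
        completers = {p for p, lw in last_active.items() if lw >= weeks}
        n_esc = int((safety[
            safety["participant_id"].isin(completers)
            & (safety["kind"] == ActionKind.ESCALATE.value)
        ]).shape[0]) if len(safety) else 0
        uniq = safety[
            safety["participant_id"].isin(completers)
            & (safety["kind"] == ActionKind.ESCALATE.value)
        ]["participant_id"].nunique() if len(safety) else 0
        rate = round(100.0 * uniq / len(completers), 1) if completers else 0.0
        escalations = (n_esc, int(uniq), rate)

    return OutcomeReport(
        change_tables=change_tables,
        transitions=transitions,
        engagement_weekly=weekly,
        engagement_summary=summary,
        flow=flow,
        checkin_summary=checkin_summary,
        escalations=escalations,
    )
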