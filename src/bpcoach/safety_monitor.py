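"""Critical-reading safety pathway: remeasure prompts, escalation, rate limit.

Per participant, sessions are processed in chronological order. A critical
session mean (SBP > 180 or DBP > 110, or SBP < 90 or DBP < 60) first triggers
a remeasure prompt; a second critical session in a row escalates to the care
team. Escalation notifications are limited to one per participant-week
(participant-anchored study weeks); an escalation due while the limit is spent
is recorded as suppressed. Any non-critical session resets the consecutive
counter. High and low criticals share one counter.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Tuple

from .core_types import (
    BPSession,
    CriticalFlag,
    ValidationError,
    assign_week,
    flag_critical,
)


class ActionKind(str, enum.Enum):
    NONE = "none"
    REMEASURE_PROMPT = "remeasure_prompt"
    ESCALATE = "escalate"
    ESCALATE_SUPPRESSED = "escalate_suppressed"


@dataclass(frozen=True)
class SafetyState:
    participant_id: str
    onboarding_day: _dt.date
    consecutive_critical: int = 0
    last_notification_week: Optional[int] = None
    last_timestamp: Optional[_dt.datetime] = None


@dataclass(frozen=True)
class SafetyAction:
    kind: ActionKind
    participant_id: str
    timestamp: _dt.datetime
    week: int
    flag: CriticalFlag


def process_session(state: SafetyState, session: BPSession) -> Tuple[SafetyState, SafetyAction]:
    """Advance the per-participant safety state machine by one session."""
    if state.last_timestamp is not None and session.timestamp < state.last_timestamp:
        raise ValidationError(
            f"{state.participant_id}: sessions must be processed chronologically"
        )
    week = assign_week(session.timestamp, state.onboarding_day).index
    flag = flag_critical(session.mean_sbp, session.mean_dbp)

    if flag is CriticalFlag.NONE:
        new = replace(state, consecutive_critical=0, last_timestamp=session.timestamp)
        kind = ActionKind.NONE
    else:
        count = state.consecutive_critical + 1
        if count == 1:
            kind = ActionKind.REMEASURE_PROMPT
            new = replace(state, consecutive_critical=count,
                          last_timestamp=session.timestamp)
        elif state.last_notification_week != week:
            kind = ActionKind.ESCALATE
            new = replace(state, consecutive_critical=count,
                          last_notification_week=week,
                          last_timestamp=session.timestamp)
        else:
            kind = ActionKind.ESCALATE_SUPPRESSED
            new = replace(state, consecutive_critical=count,
                          last_timestamp=session.timestamp)
    return new, SafetyAction(kind, state.participant_id, session.timestamp, week, flag)


def summarize_escalations(
    actions: Iterable[SafetyAction],
    cohort_size: int,
) -> Tuple[int, int, float]:
    """Escalation counts over a log: (notifications, unique patients, rate %).

    Only kind=escalate counts; the unique-patient rate is per the given cohort
    size, one decimal.
    """
    escalations = [a for a in actions if a.kind is ActionKind.ESCALATE]
    patients = {a.participant_id for a in escalations}
    rate = round(100.0 * len(patients) / cohort_size, 1) if cohort_size else 0.0
    return len(escalations), len(patients), rate
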