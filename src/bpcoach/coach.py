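"""Weekly recommendation selection, message composition, check-in bookkeeping.

The coach asks each participant to concentrate on one aspect of their
lifestyle at a time — the factor with the greatest modelled association with
their BP. A 37-item catalog maps every lifestyle factor to concrete,
actionable recommendations; within a factor the coach rotates through items
not yet sent to the participant. A factor refused twice in a row at high
difficulty (>= 4) is rested for two weeks in favour of the next-ranked factor,
so the advice stays within the participant's ability. Before a personal model
exists (cold start) a fixed generic rotation is used:
activity -> sleep -> salt -> stress.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core_types import HEALTHY_DIRECTION, ValidationError
from .personal_model import FactorImpact


@dataclass(frozen=True)
class Recommendation:
    rec_id: int
    factor: str
    text: str
    healthy_direction: int


@dataclass(frozen=True)
class BPSummary:
    mean_sbp: Optional[float]
    mean_dbp: Optional[float]
    delta_sbp: Optional[float]
    delta_dbp: Optional[float]

    @property
    def available(self) -> bool:
        return self.mean_sbp is not None


@dataclass(frozen=True)
class RecommendationEvent:
    participant_id: str
    week: int
    rec_id: int
    factor: str
    bp_summary: BPSummary
    delivered_at: Optional[_dt.datetime] = None


@dataclass(frozen=True)
class CheckIn:
    participant_id: str
    week: int
    rec_id: int
    followed: bool
    difficulty: int

    def __post_init__(self) -> None:
        if not 1 <= self.difficulty <= 5:
            raise ValidationError(f"difficulty must be in 1..5, got {self.difficulty}")


def _rec(rec_id: int, factor: str, text: str) -> Recommendation:
    return Recommendation(rec_id, factor, text, HEALTHY_DIRECTION[factor])


#: Default 37-item catalog covering every modelled lifestyle factor.
DEFAULT_CATALOG: Tuple[Recommendation, ...] = (
    # activity / steps
    _rec(1, "steps", "Add a 15-minute walk after lunch to raise your daily steps."),
    _rec(2, "steps", "Aim for 500 more steps per day than last week."),
    _rec(3, "steps", "Take the stairs instead of the elevator whenever possible."),
    _rec(4, "steps", "Park farther away or get off one stop early to add steps."),
    _rec(5, "steps", "Take a short walking break every 2 hours of sitting."),
    _rec(6, "steps", "Plan one longer walk (30+ minutes) this weekend."),
    # active minutes
    _rec(7, "active_minutes", "Schedule 20 minutes of brisk activity 3 days this week."),
    _rec(8, "active_minutes", "Try a 10-minute mobility or stretching session each morning."),
    _rec(9, "active_minutes", "Do light strength exercises twice this week."),
    _rec(10, "active_minutes", "Cycle or swim once this week for at least 20 minutes."),
    # sleep duration & hygiene
    _rec(11, "sleep_duration", "Go to bed 30 minutes earlier each night this week."),
    _rec(12, "sleep_duration", "Keep a consistent bedtime and wake time, including weekends."),
    _rec(13, "sleep_duration", "Avoid screens for the hour before bed."),
    _rec(14, "sleep_duration", "Skip caffeine after 2 PM to protect your sleep."),
    _rec(15, "sleep_duration", "Keep your bedroom cool, dark, and quiet tonight."),
    _rec(16, "sleep_duration", "Aim for at least 7 hours in bed every night this week."),
    # resting heart rate (conditioning / recovery)
    _rec(17, "resting_hr", "Add one easy cardio session to improve your resting heart rate."),
    _rec(18, "resting_hr", "Practice 5 minutes of slow breathing before bed to aid recovery."),
    # stress
    _rec(19, "stress", "Try a 10-minute guided meditation on 3 days this week."),
    _rec(20, "stress", "Practice slow diaphragmatic breathing for 5 minutes daily."),
    _rec(21, "stress", "Take a short outdoor break when you notice stress building."),
    _rec(22, "stress", "Write down three things that went well at the end of each day."),
    _rec(23, "stress", "Block out 15 unscheduled minutes for yourself each day."),
    # mood
    _rec(24, "mood", "Plan one enjoyable social activity this week."),
    _rec(25, "mood", "Spend 20 minutes on a hobby you enjoy at least twice this week."),
    # alcohol
    _rec(26, "alcohol_servings", "Keep at least 3 alcohol-free days this week."),
    _rec(27, "alcohol_servings", "Limit yourself to one drink on days you do drink."),
    _rec(28, "alcohol_servings", "Swap your usual drink for a non-alcoholic option twice this week."),
    # red meat
    _rec(29, "red_meat_servings", "Replace red meat with fish or poultry twice this week."),
    _rec(30, "red_meat_servings", "Try one fully plant-based dinner this week."),
    _rec(31, "red_meat_servings", "Choose lean cuts and smaller portions when eating red meat."),
    # fruits & vegetables
    _rec(32, "fruit_veg_servings", "Add one serving of vegetables to lunch and dinner."),
    _rec(33, "fruit_veg_servings", "Have fruit instead of a processed snack once a day."),
    _rec(34, "fruit_veg_servings", "Fill half your plate with vegetables at dinner."),
    # salt
    _rec(35, "salt_level", "Cook at home without added salt; season with herbs instead."),
    _rec(36, "salt_level", "Check labels and pick low-sodium options this week."),
    _rec(37, "salt_level", "Avoid salty processed snacks; keep unsalted alternatives handy."),
)

assert len(DEFAULT_CATALOG) == 37
assert len({r.rec_id for r in DEFAULT_CATALOG}) == 37

#: Cold-start rotation before a personal model can be fitted.
GENERIC_ROTATION: Tuple[str, ...] = ("steps", "sleep_duration", "salt_level", "stress")

#: Weeks a factor is rested after two consecutive high-difficulty refusals.
SKIP_WEEKS = 2
SKIP_DIFFICULTY = 4


def _skipped_factors(
    history: Sequence[Tuple[RecommendationEvent, Optional[CheckIn]]],
    week: int,
) -> set:
    """Factors resting this week under the difficulty-based skip rule."""
    by_factor: Dict[str, List[CheckIn]] = {}
    for event, checkin in history:
        if checkin is not None:
            by_factor.setdefault(event.factor, []).append(checkin)
    skipped = set()
    for factor, checkins in by_factor.items():
        checkins = sorted(checkins, key=lambda c: c.week)
        if len(checkins) < 2:
            continue
        last2 = checkins[-2:]
        if all((not c.followed) and c.difficulty >= SKIP_DIFFICULTY for c in last2):
            if week - last2[-1].week <= SKIP_WEEKS:
                skipped.add(factor)
    return skipped


def select_recommendation(
    ranking: Optional[Sequence[FactorImpact]],
    history: Sequence[Tuple[RecommendationEvent, Optional[CheckIn]]],
    week: int,
    catalog: Sequence[Recommendation] = DEFAULT_CATALOG,
    skip_rule: bool = True,
) -> Recommendation:
    """Pick this week's recommendation.

    The highest-ranked factor wins, unless the skip rule rests it; with no
    ranking (cold start) the generic rotation cycles. Within a factor, items
    the participant has not yet received are preferred (lowest rec_id first),
    then the least-sent item.
    """
    if not catalog:
        raise ValidationError("recommendation catalog is empty")
    by_factor: Dict[str, List[Recommendation]] = {}
    for rec in sorted(catalog, key=lambda r: r.rec_id):
        by_factor.setdefault(rec.factor, []).append(rec)

    skipped = _skipped_factors(history, week) if skip_rule else set()

    candidates: List[str]
    if ranking:
        candidates = [fi.factor for fi in sorted(ranking, key=lambda f: f.rank)
                      if fi.factor in by_factor]
    else:
        n_cold = sum(1 for e, _ in history)
        start = n_cold % len(GENERIC_ROTATION)
        candidates = list(GENERIC_ROTATION[start:] + GENERIC_ROTATION[:start])
    eligible = [f for f in candidates if f not in skipped] or candidates
    factor = eligible[0]

    sent_counts: Dict[int, int] = {}
    for event, _ in history:
        sent_counts[event.rec_id] = sent_counts.get(event.rec_id, 0) + 1
    options = by_factor[factor]
    unsent = [r for r in options if sent_counts.get(r.rec_id, 0) == 0]
    if unsent:
        return unsent[0]
    return min(options, key=lambda r: (sent_counts.get(r.rec_id, 0), r.rec_id))


def compose_weekly_message(
    participant_id: str,
    week: int,
    recommendation: Recommendation,
    week_sessions: Sequence[Tuple[float, float]],
    prev_week_sessions: Sequence[Tuple[float, float]],
    existing_events: Sequence[RecommendationEvent] = (),
    delivered_at: Optional[_dt.datetime] = None,
) -> RecommendationEvent:
    """Compose the weekly message event with its BP progress summary.

    ``week_sessions``/``prev_week_sessions`` are (mean_sbp, mean_dbp) session
    values for the current and previous week; empty means no data, in which
    case the summary is marked unavailable but the recommendation is still
    sent. Duplicate delivery for the same participant-week is rejected.
    """
    for e in existing_events:
        if e.participant_id == participant_id and e.week == week:
            raise ValidationError(
                f"duplicate recommendation for {participant_id} week {week}"
            )

    def _mean(vals: Sequence[Tuple[float, float]]):
        if not vals:
            return None, None
        return (sum(v[0] for v in vals) / len(vals),
                sum(v[1] for v in vals) / len(vals))

    s_now, d_now = _mean(week_sessions)
    s_prev, d_prev = _mean(prev_week_sessions)
    delta_s = s_now - s_prev if (s_now is not None and s_prev is not None) else None
    delta_d = d_now - d_prev if (d_now is not None and d_prev is not None) else None
    return RecommendationEvent(
        participant_id=participant_id,
        week=week,
        rec_id=recommendation.rec_id,
        factor=recommendation.factor,
        bp_summary=BPSummary(s_now, d_now, delta_s, delta_d),
        delivered_at=delivered_at,
    )


@dataclass(frozen=True)
class CheckInSummary:
    n: int
    follow_rate: float                      # percent, 2 decimals
    mean_difficulty_followed: Optional[float]
    mean_difficulty_not_followed: Optional[float]
    histogram: Dict[Tuple[int, bool], int]  # (difficulty, followed) -> count


def aggregate_checkins(checkins: Iterable[CheckIn]) -> CheckInSummary:
    """Follow rate (percent, 2 decimals), difficulty means and histogram."""
    checkins = list(checkins)
    if not checkins:
        raise ValidationError("aggregate_checkins needs at least one check-in")
    followed = [c for c in checkins if c.followed]
    refused = [c for c in checkins if not c.followed]
    hist: Dict[Tuple[int, bool], int] = {}
    for c in checkins:
        key = (c.difficulty, c.followed)
        hist[key] = hist.get(key, 0) + 1
    return CheckInSummary(
        n=len(checkins),
        follow_rate=round(100.0 * len(followed) / len(checkins), 2),
        mean_difficulty_followed=(
            sum(c.difficulty for c in followed) / len(followed) if followed else None
        ),
        mean_difficulty_not_followed=(
            sum(c.difficulty for c in refused) / len(refused) if refused else None
        ),
        histogram=hist,
    )
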