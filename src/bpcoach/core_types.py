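"""Shared domain types and blood-pressure semantics.

This module holds the vocabulary every other part of the package speaks:
blood-pressure readings and measurement sessions, the 2017 ACC/AHA category
thresholds (controlled < 130/80; stage 1 = SBP 130-139 or DBP 80-89; stage 2 =
SBP >= 140 or DBP >= 90), the critical-reading thresholds used by the safety
pathway (SBP > 180 or DBP > 110 high; SBP < 90 or DBP < 60 low), daily
lifestyle records, and the participant-anchored 7-day study-week convention.

Categories are applied to real-valued session means with the strict/inclusive
boundaries exactly as defined above; values are never rounded before
classification.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple


class ValidationError(ValueError):
    """Raised when a domain value violates its declared invariants."""


# ---------------------------------------------------------------------------
# Lifestyle factor vocabulary
# ---------------------------------------------------------------------------

#: Ordered set of lifestyle factors used as model features. The first four
#: come from the wearable stream, the rest from the daily questionnaire.
LIFESTYLE_FACTORS: Tuple[str, ...] = (
    "steps",
    "active_minutes",
    "sleep_duration",
    "resting_hr",
    "stress",
    "mood",
    "alcohol_servings",
    "red_meat_servings",
    "fruit_veg_servings",
    "salt_level",
)

WEARABLE_FACTORS: Tuple[str, ...] = LIFESTYLE_FACTORS[:4]
QUESTIONNAIRE_FACTORS: Tuple[str, ...] = LIFESTYLE_FACTORS[4:]

#: Physiological sign of each factor's association with BP: +1 means "more of
#: this raises BP" (salt, stress, alcohol...), -1 means "more lowers BP"
#: (steps, sleep, mood...).
BP_SIGN = {
    "steps": -1,
    "active_minutes": -1,
    "sleep_duration": -1,
    "resting_hr": +1,
    "stress": +1,
    "mood": -1,
    "alcohol_servings": +1,
    "red_meat_servings": +1,
    "fruit_veg_servings": -1,
    "salt_level": +1,
}

#: Direction of factor change that is expected to lower BP.
HEALTHY_DIRECTION = {f: -s for f, s in BP_SIGN.items()}


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------


class BPCategory(str, enum.Enum):
    CONTROLLED = "controlled"
    STAGE1 = "stage1"
    STAGE2 = "stage2"


class CriticalFlag(str, enum.Enum):
    NONE = "none"
    HIGH = "high"
    LOW = "low"


class Slot(str, enum.Enum):
    MORNING = "morning"
    EVENING = "evening"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


def _check_pressure(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValidationError(f"{name} must be a finite positive pressure, got {value!r}")


@dataclass(frozen=True)
class BPReading:
    """One cuff reading: systolic/diastolic pressure in mm Hg, optional pulse."""

    sbp: float
    dbp: float
    pulse: Optional[float] = None

    def __post_init__(self) -> None:
        _check_pressure("sbp", self.sbp)
        _check_pressure("dbp", self.dbp)
        if self.sbp <= self.dbp:
            raise ValidationError(f"sbp ({self.sbp}) must exceed dbp ({self.dbp})")
        if self.pulse is not None and not (math.isfinite(self.pulse) and self.pulse > 0):
            raise ValidationError(f"pulse must be finite positive, got {self.pulse!r}")


def session_mean(readings: Sequence[BPReading]) -> Tuple[float, float]:
    """Component-wise arithmetic mean of 1-3 consecutive readings.

    The protocol asks for 3 consecutive readings per session and uses their
    average as the session value; sessions with fewer readings are averaged
    over what is available.
    """
    if not 1 <= len(readings) <= 3:
        raise ValidationError(f"a session holds 1-3 readings, got {len(readings)}")
    n = len(readings)
    return (
        sum(r.sbp for r in readings) / n,
        sum(r.dbp for r in readings) / n,
    )


@dataclass(frozen=True)
class BPSession:
    """One measurement session (morning or evening set of consecutive readings)."""

    participant_id: str
    timestamp: _dt.datetime
    slot: Slot
    readings: Tuple[BPReading, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "readings", tuple(self.readings))
        session_mean(self.readings)  # validates count

    @property
    def mean_sbp(self) -> float:
        return session_mean(self.readings)[0]

    @property
    def mean_dbp(self) -> float:
        return session_mean(self.readings)[1]


@dataclass(frozen=True)
class DailyLifestyle:
    """One participant-day of wearable and questionnaire features.

    Any field may be absent (None); absence is never encoded as 0. Ordinal
    items (stress, mood, salt_level) live on a 1-5 scale; counts are
    non-negative.
    """

    participant_id: str
    date: _dt.date
    steps: Optional[float] = None
    active_minutes: Optional[float] = None
    walk_run_speed: Optional[float] = None
    sleep_duration: Optional[float] = None
    bedtime: Optional[str] = None
    uptime: Optional[str] = None
    deep_min: Optional[float] = None
    light_min: Optional[float] = None
    rem_min: Optional[float] = None
    awake_min: Optional[float] = None
    resting_hr: Optional[float] = None
    stress: Optional[int] = None
    mood: Optional[int] = None
    alcohol_servings: Optional[float] = None
    red_meat_servings: Optional[float] = None
    fruit_veg_servings: Optional[float] = None
    salt_level: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("steps", "active_minutes", "sleep_duration", "deep_min",
                     "light_min", "rem_min", "awake_min", "alcohol_servings",
                     "red_meat_servings", "fruit_veg_servings"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        for name in ("stress", "mood", "salt_level"):
            v = getattr(self, name)
            if v is not None and not 1 <= v <= 5:
                raise ValidationError(f"{name} must be in 1..5, got {v}")
        stages = [v for v in (self.deep_min, self.light_min, self.rem_min) if v is not None]
        if stages and self.sleep_duration is not None:
            budget = self.sleep_duration + (self.awake_min or 0.0)
            if sum(stages) > budget + 1e-9:
                raise ValidationError("sleep-stage minutes exceed sleep_duration + awake_min")


@dataclass(frozen=True)
class StudyWeek:
    """A participant-anchored 7-day block; week w covers days 7(w-1)+1 .. 7w
    counted from the participant's first study day."""

    index: int

    def __post_init__(self) -> None:
        if not (isinstance(self.index, int) and self.index >= 1):
            raise ValidationError(f"week index must be an integer >= 1, got {self.index!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def classify_bp(sbp: float, dbp: float) -> BPCategory:
    """Classify a (mean) BP value into controlled / stage-1 / stage-2.

    Stage 2 iff SBP >= 140 or DBP >= 90; else stage 1 iff SBP >= 130 or
    DBP >= 80; else controlled. Exactly one category applies to any pair.
    """
    _check_pressure("sbp", sbp)
    _check_pressure("dbp", dbp)
    if sbp >= 140 or dbp >= 90:
        return BPCategory.STAGE2
    if sbp >= 130 or dbp >= 80:
        return BPCategory.STAGE1
    return BPCategory.CONTROLLED


def flag_critical(mean_sbp: float, mean_dbp: float) -> CriticalFlag:
    """Critical-reading check on session means (strict inequalities).

    High iff SBP > 180 or DBP > 110; low iff SBP < 90 or DBP < 60. Were a
    reading somehow to satisfy both, high wins.
    """
    _check_pressure("mean_sbp", mean_sbp)
    _check_pressure("mean_dbp", mean_dbp)
    if mean_sbp > 180 or mean_dbp > 110:
        return CriticalFlag.HIGH
    if mean_sbp < 90 or mean_dbp < 60:
        return CriticalFlag.LOW
    return CriticalFlag.NONE


def _as_date(d: "_dt.date | _dt.datetime") -> _dt.date:
    return d.date() if isinstance(d, _dt.datetime) else d


def assign_week(timestamp: "_dt.date | _dt.datetime",
                onboarding_day: "_dt.date | _dt.datetime") -> StudyWeek:
    """Map a timestamp to the participant-anchored study week.

    Day 1 is the onboarding day; days 1-7 are week 1, days 8-14 week 2, etc.
    Timestamps before onboarding are rejected.
    """
    days = (_as_date(timestamp) - _as_date(onboarding_day)).days
    if days < 0:
        raise ValidationError("timestamp precedes onboarding day")
    return StudyWeek(days // 7 + 1)


def week_of_day(day: int) -> int:
    """Week index for a 1-based study day number."""
    if day < 1:
        raise ValidationError(f"study days are 1-based, got {day}")
    return (day - 1) // 7 + 1
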