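"""Synthetic hypertension cohort with closed-loop coaching response.

Generates participants, daily lifestyle/BP streams, adherence behaviour and
rolling dropout with the statistical structure the intervention assumes, so
every downstream module is testable without device data.

Per-patient ground truth plants a linear lifestyle -> BP model: each session
mean is

    baseline + sum_f coef_f * z_f(previous-day latent value) + noise,

with ``coef_f`` in mm Hg per 1 SD of factor f and z-scores taken against the
population-nominal factor scale. Latent daily behaviour always exists;
missingness only hides records from the emitted files. Coaching closes the
loop: when a weekly recommendation is followed (a Bernoulli draw whose
probability decreases logistically with perceived difficulty, calibrated so
the marginal follow rate over a uniform difficulty mix matches the trial's
63.64%), the targeted factor's latent mean shifts one configurable step in
its healthy direction starting the following week, and the shift decays
without reinforcement.

Dropout is a per-week Bernoulli hazard with separate phases (weeks 1-12 and
13 onward), each calibrated to a cumulative target. All randomness is keyed
``SeedSequence([seed, participant, week, stream])`` so identical configs give
byte-identical streams and adding participants never perturbs existing ones.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .core_types import (
    BP_SIGN,
    BPCategory,
    HEALTHY_DIRECTION,
    LIFESTYLE_FACTORS,
    QUESTIONNAIRE_FACTORS,
    WEARABLE_FACTORS,
    ValidationError,
    week_of_day,
)
from .coach import CheckIn, Recommendation, RecommendationEvent

N_FACTORS = len(LIFESTYLE_FACTORS)
N_WEARABLE = len(WEARABLE_FACTORS)

# Population-nominal factor scales used for z-scoring planted effects and for
# behaviour shifts (mean, SD on the raw scale, drawing family).
FACTOR_SCALE: Dict[str, Tuple[float, float]] = {
    "steps": (8000.0, 3300.0),
    "active_minutes": (35.0, 20.0),
    "sleep_duration": (420.0, 60.0),
    "resting_hr": (68.0, 8.0),
    "stress": (2.85, 1.15),
    "mood": (3.45, 1.05),
    "alcohol_servings": (0.6, 0.78),
    "red_meat_servings": (0.5, 0.71),
    "fruit_veg_servings": (2.5, 1.58),
    "salt_level": (3.0, 1.1),
}

ORDINAL_FACTORS = ("stress", "mood", "salt_level")
COUNT_FACTORS = ("alcohol_servings", "red_meat_servings", "fruit_veg_servings")

# Baseline BP (mean SBP, SD, mean DBP, SD) by planted category, consistent
# with a cohort recruited on recent stage-2 clinical readings.
CATEGORY_BP = {
    BPCategory.CONTROLLED: (121.4, 6.1, 74.2, 4.4),
    BPCategory.STAGE1: (128.8, 7.1, 82.2, 6.4),
    BPCategory.STAGE2: (141.9, 9.3, 89.4, 8.0),
}

STUDY_EPOCH = _dt.date(2021, 11, 1)

# RNG stream codes
_PROFILE, _BEHAVIOR, _CHECKIN, _DROPOUT = 0, 1, 2, 3


def follow_probability(difficulty: float, intercept: float, slope: float) -> float:
    """Probability a recommendation is followed; strictly decreasing in
    difficulty for slope > 0."""
    return float(expit(intercept - slope * difficulty))


def calibrate_follow_intercept(
    target_rate: float, slope: float, difficulties: Sequence[int] = (1, 2, 3, 4, 5)
) -> float:
    """Intercept such that the mean follow probability over the given
    difficulty mix equals ``target_rate``."""
    def gap(a: float) -> float:
        return np.mean([follow_probability(d, a, slope) for d in difficulties]) - target_rate
    return float(brentq(gap, -20.0, 30.0))


def phase_hazard(cumulative: float, n_weeks: int) -> float:
    """Constant per-week hazard with the given cumulative dropout over
    ``n_weeks`` weeks."""
    if not 0.0 <= cumulative < 1.0:
        raise ValidationError("cumulative dropout must be in [0, 1)")
    return 1.0 - (1.0 - cumulative) ** (1.0 / n_weeks)


@dataclass(frozen=True)
class PatientTruth:
    """Planted ground truth for one synthetic participant (testing only;
    never written into the data streams)."""

    participant_id: str
    onboard_date: _dt.date
    baseline_category: BPCategory
    baseline_sbp: float
    baseline_dbp: float
    coef: Dict[str, float]          # mm Hg per 1 SD of each factor
    noise_sd: float
    med_flag: bool
    adherence_slope: float          # difficulty sensitivity (logistic slope)
    follow_intercept: float
    dropout_hazard: Tuple[float, float]
    dominant_factor: Optional[str] = None
    withdraw_week: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not all(math.isfinite(v) for v in self.coef.values()):
            raise ValidationError("coefficients must be finite")


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the trial: 141 onboarded participants followed 24 weeks,
    1-2 daily sessions of 3 readings, a baseline category mix of 38/48/55
    (controlled / stage 1 / stage 2), ~83.7% on antihypertensive medication,
    cumulative dropout 9.2% by week 12 and 20.3% from week 12 to 24, weekly
    task participation near the observed 93/94/88% engagement rates, and a
    follow-probability curve whose marginal rate is 63.64% over a uniform
    difficulty mix.
    """

    n_participants: int = 141
    weeks: int = 24
    seed: int = 0
    baseline_mix: Tuple[float, float, float] = (38 / 141, 48 / 141, 55 / 141)
    noise_sd: float = 6.0
    dbp_effect_ratio: float = 0.6
    reading_jitter_sd: float = 3.0
    med_rate: float = 0.837
    # effect sizes (mm Hg per SD): every factor gets a background magnitude,
    # a few salient factors get boosted ones
    coef_background: Tuple[float, float] = (0.1, 0.8)
    coef_salient: Tuple[float, float] = (1.5, 3.5)
    n_salient: Tuple[int, int] = (2, 4)
    # dominant-factor recovery-test mode: one factor >= 3x all others
    dominant_factor_mode: bool = False
    dominant_magnitude: Tuple[float, float] = (3.5, 5.0)
    dominant_ratio: float = 3.0
    # adherence
    follow_slope: float = 1.0
    follow_rate_target: float = 0.6364
    adherence_slope_range: Tuple[float, float] = (1.0, 1.0)
    behavior_step: float = 0.4      # SD units per followed recommendation
    behavior_decay: float = 0.85    # weekly decay without reinforcement
    behavior_cap: float = 2.0       # SD units
    coaching: bool = True
    # dropout (phase 1 = weeks 1..12, phase 2 = weeks 13..weeks)
    dropout_by_week12: float = 0.092
    dropout_12_to_24: float = 0.203
    # engagement / missingness
    weekly_bp_p: float = 0.93
    weekly_wear_p: float = 0.94
    weekly_quest_p: float = 0.88
    daily_bp_p: float = 0.75
    second_session_p: float = 0.35
    daily_wear_p: float = 0.90
    daily_quest_p: float = 0.70
    # physiological box for baseline draws: keeps sustained session means
    # clear of the critical thresholds so critical readings come from acute
    # spike episodes rather than a patient's resting level
    baseline_sbp_bounds: Tuple[float, float] = (110.0, 165.0)
    baseline_dbp_bounds: Tuple[float, float] = (74.0, 96.0)
    # rare 2-day hypertensive spike episodes so the safety pathway fires
    spike_daily_p: float = 0.0006
    spike_magnitude: Tuple[float, float] = (45.0, 25.0)
    # funnel context (upstream of onboarding)
    contacted: int = 274
    consented: int = 164
    onboard_stagger_days: int = 455

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValidationError("n_participants must be >= 0")
        if self.weeks < 1:
            raise ValidationError("weeks must be >= 1")
        if abs(sum(self.baseline_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.baseline_mix):
            raise ValidationError("baseline_mix must be non-negative and sum to 1")
        self.follow_intercept_base = calibrate_follow_intercept(
            self.follow_rate_target, self.follow_slope
        )
        self.hazard_phase1 = phase_hazard(self.dropout_by_week12, 12)
        self.hazard_phase2 = phase_hazard(self.dropout_12_to_24, 12)


@dataclass
class GeneratedCohort:
    """Everything one simulation run produced."""

    config: CohortConfig
    truths: List[PatientTruth]
    bp_sessions: pd.DataFrame
    lifestyle_daily: pd.DataFrame
    questionnaire_daily: pd.DataFrame
    recommendations: List[RecommendationEvent] = field(default_factory=list)
    checkins: List[CheckIn] = field(default_factory=list)

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = {
                "participant_id": t.participant_id,
                "onboard_date": t.onboard_date.isoformat(),
                "baseline_category": t.baseline_category.value,
                "baseline_sbp": t.baseline_sbp,
                "baseline_dbp": t.baseline_dbp,
                "noise_sd": t.noise_sd,
                "med_flag": t.med_flag,
                "adherence_slope": t.adherence_slope,
                "follow_intercept": t.follow_intercept,
                "dominant_factor": t.dominant_factor or "",
                "withdraw_week": t.withdraw_week,
            }
            for f in LIFESTYLE_FACTORS:
                row[f"coef_{f}"] = t.coef[f]
            rows.append(row)
        return pd.DataFrame(rows)


def _rng(config_seed: int, participant: int, week: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config_seed, participant, week, stream])
    )


def _draw_truth(config: CohortConfig, idx: int) -> PatientTruth:
    rng = _rng(config.seed, idx, 0, _PROFILE)
    pid = f"P{idx + 1:04d}"
    cat = [BPCategory.CONTROLLED, BPCategory.STAGE1, BPCategory.STAGE2][
        int(rng.choice(3, p=config.baseline_mix))
    ]
    mu_s, sd_s, mu_d, sd_d = CATEGORY_BP[cat]
    from .core_types import classify_bp

    s_lo, s_hi = config.baseline_sbp_bounds
    d_lo, d_hi = config.baseline_dbp_bounds
    sbp = dbp = None
    for _ in range(500):
        s = float(rng.normal(mu_s, sd_s))
        d = float(rng.normal(mu_d, sd_d))
        if not (s_lo <= s <= s_hi and d_lo <= d <= d_hi):
            continue
        if d >= s - 20:  # keep a physiological pulse pressure
            continue
        if classify_bp(s, d) is cat:
            sbp, dbp = s, d
            break
    if sbp is None:  # fall back to the category center
        sbp, dbp = mu_s, max(min(mu_d, d_hi), d_lo)

    coef: Dict[str, float] = {}
    if config.dominant_factor_mode:
        dominant = str(rng.choice(LIFESTYLE_FACTORS))
        lo, hi = config.coef_background
        for f in LIFESTYLE_FACTORS:
            coef[f] = BP_SIGN[f] * float(rng.uniform(lo, hi))
        mag = float(rng.uniform(*config.dominant_magnitude))
        mag = max(mag, config.dominant_ratio * max(abs(v) for v in coef.values()))
        coef[dominant] = BP_SIGN[dominant] * mag
    else:
        dominant = None
        lo, hi = config.coef_background
        for f in LIFESTYLE_FACTORS:
            coef[f] = BP_SIGN[f] * float(rng.uniform(lo, hi))
        n_sal = int(rng.integers(config.n_salient[0], config.n_salient[1] + 1))
        salient = rng.choice(N_FACTORS, size=n_sal, replace=False)
        for j in salient:
            f = LIFESTYLE_FACTORS[j]
            coef[f] = BP_SIGN[f] * float(rng.uniform(*config.coef_salient))

    slope_mult = float(rng.uniform(*config.adherence_slope_range))
    slope = config.follow_slope * slope_mult
    intercept = (
        config.follow_intercept_base
        if slope_mult == 1.0
        else calibrate_follow_intercept(config.follow_rate_target, slope)
    )
    onboard = STUDY_EPOCH + _dt.timedelta(
        days=int(rng.integers(0, config.onboard_stagger_days + 1))
    )
    return PatientTruth(
        participant_id=pid,
        onboard_date=onboard,
        baseline_category=cat,
        baseline_sbp=sbp,
        baseline_dbp=dbp,
        coef=coef,
        noise_sd=config.noise_sd,
        med_flag=bool(rng.random() < config.med_rate),
        adherence_slope=slope,
        follow_intercept=intercept,
        dropout_hazard=(config.hazard_phase1, config.hazard_phase2),
        dominant_factor=dominant,
    )


def _draw_latent_day(
    rng: np.random.Generator, offsets: np.ndarray
) -> np.ndarray:
    """Latent (continuous) factor values for one day, behaviour offsets
    applied in each factor's healthy direction."""
    vals = np.empty(N_FACTORS)
    for j, f in enumerate(LIFESTYLE_FACTORS):
        mean, sd = FACTOR_SCALE[f]
        if f == "steps":
            sigma = 0.4
            mu = math.log(mean) - 0.5 * sigma**2
            v = float(rng.lognormal(mu, sigma))
        else:
            v = float(rng.normal(mean, sd))
        v += offsets[j] * sd * HEALTHY_DIRECTION[f]
        if f in COUNT_FACTORS or f == "steps" or f == "active_minutes":
            v = max(v, 0.0)
        vals[j] = v
    return vals


def _zscores(latent: np.ndarray) -> np.ndarray:
    out = np.empty(N_FACTORS)
    for j, f in enumerate(LIFESTYLE_FACTORS):
        mean, sd = FACTOR_SCALE[f]
        out[j] = (latent[j] - mean) / sd
    return out


def _emit_value(f: str, v: float) -> float:
    """Round/clip a latent value into its recorded form."""
    if f in ORDINAL_FACTORS:
        return int(min(5, max(1, round(v))))
    if f in COUNT_FACTORS:
        return int(max(0, round(v)))
    if f in ("steps",):
        return int(round(max(v, 0)))
    return round(max(v, 0.0), 1)


def simulate_response(
    truth: PatientTruth,
    recommendation: Recommendation,
    difficulty: int,
    rng: np.random.Generator,
    step: float = 0.4,
) -> Tuple[CheckIn, Dict[str, float]]:
    """Simulate the midweek check-in for a delivered recommendation.

    Followed ~ Bernoulli(p(difficulty)) with p strictly decreasing in
    difficulty. If followed, the targeted factor shifts ``step`` SD in its
    healthy direction for the following week (returned as the behaviour
    delta; the caller applies and decays it).
    """
    if not 1 <= difficulty <= 5:
        raise ValidationError(f"difficulty must be in 1..5, got {difficulty}")
    p = follow_probability(difficulty, truth.follow_intercept, truth.adherence_slope)
    followed = bool(rng.random() < p)
    delta = {recommendation.factor: step} if followed else {}
    checkin = CheckIn(
        participant_id=truth.participant_id,
        week=0,  # caller rebinds to the event's week
        rec_id=recommendation.rec_id,
        followed=followed,
        difficulty=int(difficulty),
    )
    return checkin, delta


def simulate_dropout(
    truth: PatientTruth, week: int, rng: np.random.Generator
) -> bool:
    """True if the participant withdraws at the end of this week."""
    hazard = truth.dropout_hazard[0] if week <= 12 else truth.dropout_hazard[1]
    return bool(rng.random() < hazard)


class _ParticipantSim:
    """Mutable per-participant simulation state."""

    __slots__ = (
        "truth", "idx", "offsets", "pending_boost", "spike_left",
        "active", "latent", "recorded", "sessions", "events", "checkins",
        "history",
    )

    def __init__(self, truth: PatientTruth, idx: int, n_days: int):
        self.truth = truth
        self.idx = idx
        self.offsets = np.zeros(N_FACTORS)
        self.pending_boost: Dict[int, np.ndarray] = {}
        self.spike_left = 0
        self.active = True
        self.latent = np.full((n_days, N_FACTORS), np.nan)
        self.recorded = np.full((n_days, N_FACTORS), np.nan)
        self.sessions: List[Tuple[int, float, float]] = []  # (day, sbp, dbp)
        self.events: List[RecommendationEvent] = []
        self.checkins: List[CheckIn] = []
        self.history: List = []  # (event, checkin|None) pairs for the coach


def generate_cohort(
    config: CohortConfig,
    advisor: Optional[Callable] = None,
) -> GeneratedCohort:
    """Run the cohort simulation and return all streams plus ground truth.

    ``advisor(truth_id, week, recorded_matrix, sessions, history)`` returns
    the week's :class:`~bpcoach.coach.Recommendation`; if None and coaching is
    enabled, the package's model-driven coaching engine is used. With
    ``config.coaching`` False no recommendations are delivered and behaviour
    stays stationary (useful for planted-effect recovery studies).
    """
    if config.coaching and advisor is None:
        from .engine import EngineConfig, ModelCoachAdvisor

        advisor = ModelCoachAdvisor(EngineConfig(), config.seed)

    n_days = config.weeks * 7
    sims = [
        _ParticipantSim(_draw_truth(config, i), i, n_days)
        for i in range(config.n_participants)
    ]

    bp_rows: List[dict] = []
    life_rows: List[dict] = []
    quest_rows: List[dict] = []

    for week in range(1, config.weeks + 1):
        for sim in sims:
            if not sim.active:
                continue
            truth = sim.truth
            rng_b = _rng(config.seed, sim.idx, week, _BEHAVIOR)

            # behaviour kinetics: decay, then apply boosts scheduled for now
            sim.offsets *= config.behavior_decay
            boost = sim.pending_boost.pop(week, None)
            if boost is not None:
                sim.offsets += boost
            np.clip(sim.offsets, -config.behavior_cap, config.behavior_cap,
                    out=sim.offsets)

            bp_week = rng_b.random() < config.weekly_bp_p
            wear_week = rng_b.random() < config.weekly_wear_p
            quest_week = rng_b.random() < config.weekly_quest_p

            for day in range(7 * (week - 1) + 1, 7 * week + 1):
                r = day - 1
                latent = _draw_latent_day(rng_b, sim.offsets)
                sim.latent[r] = latent

                if sim.spike_left == 0 and rng_b.random() < config.spike_daily_p:
                    sim.spike_left = 2
                spike = sim.spike_left > 0
                if spike:
                    sim.spike_left -= 1

                wear_today = wear_week and rng_b.random() < config.daily_wear_p
                quest_today = quest_week and rng_b.random() < config.daily_quest_p
                date = truth.onboard_date + _dt.timedelta(days=day - 1)

                if wear_today:
                    # the model (and the replay) must see the recorded values
                    sim.recorded[r, :N_WEARABLE] = [
                        _emit_value(f, latent[j])
                        for j, f in enumerate(WEARABLE_FACTORS)
                    ]
                    sleep = _emit_value("sleep_duration", latent[2])
                    awake = round(0.08 * sleep + float(rng_b.normal(0, 3)), 1)
                    awake = max(awake, 0.0)
                    bt_min = 23 * 60 + float(rng_b.normal(0, 40))
                    bt = (_dt.datetime.combine(date, _dt.time(0, 0))
                          + _dt.timedelta(minutes=bt_min))
                    up = bt + _dt.timedelta(minutes=float(sleep) + awake)
                    life_rows.append({
                        "participant_id": truth.participant_id,
                        "date": date.isoformat(),
                        "steps": _emit_value("steps", latent[0]),
                        "active_minutes": _emit_value("active_minutes", latent[1]),
                        "walk_run_speed": (
                            round(max(float(rng_b.normal(1.3, 0.2)), 0.3), 2)
                            if rng_b.random() < 0.8 else None
                        ),
                        "sleep_duration": sleep,
                        "bedtime": bt.strftime("%H:%M"),
                        "uptime": up.strftime("%H:%M"),
                        "deep_min": round(0.15 * sleep, 1),
                        "light_min": round(0.55 * sleep, 1),
                        "rem_min": round(0.22 * sleep, 1),
                        "awake_min": awake,
                        "resting_hr": _emit_value("resting_hr", latent[3]),
                    })
                if quest_today:
                    row = {"participant_id": truth.participant_id,
                           "date": date.isoformat()}
                    for j, f in enumerate(QUESTIONNAIRE_FACTORS):
                        v = _emit_value(f, latent[N_WEARABLE + j])
                        row[f] = v
                        sim.recorded[r, N_WEARABLE + j] = v
                    quest_rows.append(row)

                if bp_week and rng_b.random() < config.daily_bp_p:
                    n_sessions = 2 if rng_b.random() < config.second_session_p else 1
                    if n_sessions == 2:
                        slots = ["morning", "evening"]
                    else:
                        slots = ["morning" if rng_b.random() < 0.6 else "evening"]
                    z = _zscores(sim.latent[r - 1] if r >= 1 else latent)
                    effect = sum(truth.coef[f] * z[j]
                                 for j, f in enumerate(LIFESTYLE_FACTORS))
                    for slot in slots:
                        noise = float(rng_b.normal(0, truth.noise_sd))
                        mean_s = truth.baseline_sbp + effect + noise
                        mean_d = (truth.baseline_dbp
                                  + config.dbp_effect_ratio * effect
                                  + config.dbp_effect_ratio * noise
                                  + float(rng_b.normal(0, 0.5 * truth.noise_sd)))
                        if spike:
                            mean_s += config.spike_magnitude[0]
                            mean_d += config.spike_magnitude[1]
                        mean_d = min(mean_d, mean_s - 15.0)
                        mean_s = max(mean_s, 70.0)
                        mean_d = max(mean_d, 40.0)
                        minute = (8 * 60 if slot == "morning" else 19 * 60) + int(
                            rng_b.integers(0, 120)
                        )
                        ts = (_dt.datetime.combine(date, _dt.time(0, 0))
                              + _dt.timedelta(minutes=minute))
                        readings = []
                        rec_s = []
                        rec_d = []
                        for _ in range(3):
                            js = float(rng_b.normal(0, config.reading_jitter_sd))
                            jd = float(rng_b.normal(0, 0.7 * config.reading_jitter_sd))
                            s_i = round(mean_s + js, 1)
                            d_i = round(min(mean_d + jd, s_i - 8.0), 1)
                            rec_s.append(s_i)
                            rec_d.append(d_i)
                        bp_rows.append({
                            "participant_id": truth.participant_id,
                            "timestamp": ts.isoformat(),
                            "slot": slot,
                            "sbp1": rec_s[0], "dbp1": rec_d[0],
                            "sbp2": rec_s[1], "dbp2": rec_d[1],
                            "sbp3": rec_s[2], "dbp3": rec_d[2],
                        })
                        sim.sessions.append(
                            (day, float(np.mean(rec_s)), float(np.mean(rec_d)))
                        )

            # midweek check-in for last week's recommendation
            if sim.events and sim.events[-1].week == week - 1:
                event = sim.events[-1]
                rng_c = _rng(config.seed, sim.idx, event.week, _CHECKIN)
                difficulty = int(rng_c.integers(1, 6))
                rec = next(r for r in _catalog_for(advisor) if r.rec_id == event.rec_id)
                checkin, delta = simulate_response(
                    truth, rec, difficulty, rng_c, step=config.behavior_step
                )
                checkin = replace(checkin, week=event.week)
                sim.checkins.append(checkin)
                sim.history[-1] = (event, checkin)
                if delta:
                    boost = np.zeros(N_FACTORS)
                    for f, v in delta.items():
                        boost[LIFESTYLE_FACTORS.index(f)] += v
                    sched = sim.pending_boost.setdefault(week + 1, np.zeros(N_FACTORS))
                    sched += boost

            # dropout at week end; withdrawn participants emit nothing further
            rng_d = _rng(config.seed, sim.idx, week, _DROPOUT)
            if simulate_dropout(truth, week, rng_d):
                sim.truth = replace(truth, withdraw_week=week)
                sim.active = False
                continue

            # weekly recommendation, delivered at the end of the week
            if config.coaching and advisor is not None:
                event = advisor.deliver(
                    truth=sim.truth,
                    week=week,
                    recorded=sim.recorded[: 7 * week],
                    sessions=sim.sessions,
                    history=sim.history,
                )
                sim.events.append(event)
                sim.history.append((event, None))

    bp = pd.DataFrame(bp_rows, columns=[
        "participant_id", "timestamp", "slot",
        "sbp1", "dbp1", "sbp2", "dbp2", "sbp3", "dbp3"])
    life = pd.DataFrame(life_rows, columns=[
        "participant_id", "date", "steps", "active_minutes", "walk_run_speed",
        "sleep_duration", "bedtime", "uptime", "deep_min", "light_min",
        "rem_min", "awake_min", "resting_hr"])
    quest = pd.DataFrame(quest_rows, columns=[
        "participant_id", "date", "stress", "mood", "alcohol_servings",
        "red_meat_servings", "fruit_veg_servings", "salt_level"])
    events = [e for sim in sims for e in sim.events]
    checkins = [c for sim in sims for c in sim.checkins]
    return GeneratedCohort(
        config=config,
        truths=[sim.truth for sim in sims],
        bp_sessions=bp,
        lifestyle_daily=life,
        questionnaire_daily=quest,
        recommendations=events,
        checkins=checkins,
    )


def _catalog_for(advisor) -> Sequence[Recommendation]:
    from .coach import DEFAULT_CATALOG

    return getattr(advisor, "catalog", DEFAULT_CATALOG)
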