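"""Synthetic reference cohorts reconstructed from the trial's published counts.

These builders assemble deterministic, session-level cohorts whose marginal
counts equal the figures the trial reported (baseline/follow-up category
counts, responder counts by subgroup, check-in tallies, escalation tallies),
so the analytics pipeline can be exercised end to end against known
arithmetic. They are synthetic stand-ins: per-participant values are
canonical category-typical BPs, not the study's (unavailable) measurements.

All outputs are plain tidy frames / domain objects accepted by the real
pipeline operations; nothing here precomputes a statistic.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from typing import List, Tuple

import pandas as pd

from .coach import CheckIn
from .core_types import BPReading, BPSession, Slot
from .safety_monitor import SafetyState, process_session

# Canonical in-category session values (SBP, DBP)
_CONTROLLED = (120.0, 75.0)
_STAGE1 = (135.0, 85.0)
_STAGE2 = (150.0, 95.0)


def _sessions(pid: str, entries: List[Tuple[int, float, float]]) -> List[dict]:
    return [{"participant_id": pid, "week": wk, "mean_sbp": s, "mean_dbp": d}
            for wk, s, d in entries]


def _cohort(rows: List[Tuple[Tuple[float, float], Tuple[float, float], int]],
            anchor: int) -> pd.DataFrame:
    """One baseline (week 1) and one follow-up (anchor week) session per
    participant, per (baseline_bp, followup_bp, count) group."""
    out: List[dict] = []
    pid = itertools.count(1)
    for base, follow, count in rows:
        for _ in range(count):
            p = f"F{next(pid):04d}"
            out.extend(_sessions(p, [(1, *base), (anchor, *follow)]))
    return pd.DataFrame(out)


def twelve_week_cohort() -> pd.DataFrame:
    """128 participants with paired week-1 / week-12 windows.

    Baseline categories 31/46/51 (controlled / stage 1 / stage 2); follow-up
    53/56/19; 58 participants with an SBP reduction >= 5 mm Hg (11/14/33 by
    baseline subgroup); 32 of 51 stage-2 participants move into lower
    categories.
    """
    rows = [
        # controlled stayers: 11 responders, 20 non-responders
        (_CONTROLLED, (114.0, 75.0), 11),
        (_CONTROLLED, (119.0, 75.0), 20),
        # stage-1 stayers: 9 responders (DBP keeps them in stage 1), 32 non
        (_STAGE1, (129.0, 85.0), 9),
        (_STAGE1, (134.0, 84.0), 32),
        # stage-1 -> controlled movers (responders)
        (_STAGE1, (121.0, 74.0), 5),
        # stage-2 stayers: 1 responder, 18 non
        (_STAGE2, (144.0, 95.0), 1),
        (_STAGE2, (149.0, 94.0), 18),
        # stage-2 -> stage-1 movers
        (_STAGE2, (135.0, 85.0), 15),
        # stage-2 -> controlled movers
        (_STAGE2, (122.0, 76.0), 17),
    ]
    assert sum(c for *_, c in rows) == 128
    return _cohort(rows, anchor=12)


def twenty_four_week_cohort() -> pd.DataFrame:
    """102 participants with paired week-1 / week-24 windows.

    Baseline categories 28/37/37; follow-up 55/37/10; 60 responders
    (14/17/29 by subgroup); 27 of 37 stage-2 participants move down.
    """
    rows = [
        (_CONTROLLED, (114.0, 75.0), 14),
        (_CONTROLLED, (119.0, 75.0), 14),
        # stage-1 stayers: none respond
        (_STAGE1, (134.0, 84.0), 19),
        # stage-1 -> controlled: 17 responders plus one small-drop mover
        # (stage 1 through DBP alone, so a 2 mm Hg SBP drop reaches controlled)
        (_STAGE1, (121.0, 74.0), 17),
        ((128.0, 85.0), (126.0, 78.0), 1),
        # stage-2 stayers: 2 responders, 8 non
        (_STAGE2, (144.0, 95.0), 2),
        (_STAGE2, (149.0, 94.0), 8),
        # stage-2 -> stage-1 / -> controlled movers
        (_STAGE2, (135.0, 85.0), 18),
        (_STAGE2, (122.0, 76.0), 9),
    ]
    assert sum(c for *_, c in rows) == 102
    return _cohort(rows, anchor=24)


def checkin_log() -> List[CheckIn]:
    """1133 midweek check-ins: 721 followed / 412 not followed, with
    difficulty tallies whose means land at 1.97 (followed) and 3.67 (not)."""
    followed_counts = {1: 300, 2: 220, 3: 140, 4: 45, 5: 16}    # n=721
    refused_counts = {1: 20, 2: 40, 3: 110, 4: 128, 5: 114}     # n=412
    out: List[CheckIn] = []
    i = itertools.count(1)
    for difficulty, n in followed_counts.items():
        for _ in range(n):
            out.append(CheckIn(f"F{next(i):04d}", 1, 1, True, difficulty))
    for difficulty, n in refused_counts.items():
        for _ in range(n):
            out.append(CheckIn(f"F{next(i):04d}", 1, 1, False, difficulty))
    return out


def _critical_pair(pid: str, onboard: _dt.date, week: int, day_in_week: int):
    base = _dt.datetime.combine(
        onboard + _dt.timedelta(days=7 * (week - 1) + day_in_week - 1),
        _dt.time(8, 0),
    )
    mk = lambda ts, s, d: BPSession(pid, ts, Slot.MORNING,
                                    (BPReading(s, d), BPReading(s + 2, d + 1),
                                     BPReading(s - 2, d - 1)))
    return [mk(base, 186.0, 96.0), mk(base + _dt.timedelta(hours=2), 188.0, 97.0)]


def escalation_log(n_patients_two: int = 5, n_patients_one: int = 1):
    """Safety-monitor action log with 2 escalations each for
    ``n_patients_two`` patients plus 1 for ``n_patients_one`` more (defaults:
    11 notifications from 6 unique patients), produced by running the real
    state machine over constructed session sequences."""
    onboard = _dt.date(2022, 1, 3)
    actions = []
    pid_iter = itertools.count(1)
    plans = [2] * n_patients_two + [1] * n_patients_one
    for n_escal in plans:
        pid = f"S{next(pid_iter):04d}"
        sessions: List[BPSession] = []
        for k in range(n_escal):
            week = 2 * k + 1
            sessions.extend(_critical_pair(pid, onboard, week, day_in_week=2))
            # normal session resets the counter between episodes
            ts = _dt.datetime.combine(
                onboard + _dt.timedelta(days=7 * week), _dt.time(9, 0))
            sessions.append(BPSession(pid, ts, Slot.MORNING,
                                      (BPReading(124.0, 78.0),)))
        state = SafetyState(participant_id=pid, onboarding_day=onboard)
        for s in sessions:
            state, action = process_session(state, s)
            actions.append(action)
    return actions
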