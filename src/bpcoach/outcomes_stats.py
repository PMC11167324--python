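"""Trial outcome analytics: windowed BP means, change and transition tables,
responder and engagement rates, cohort flow.

Conventions, matching the trial design:

* Baseline BP is the mean of all session means in study week 1; the follow-up
  value at anchor week ``a`` (12 or 24) averages all session means in weeks
  ``a-1 .. a+1``, e.g. weeks 11-13 for the 12-week outcome. Morning and
  evening sessions are weighted equally.
* Change = follow-up - baseline (negative means improvement). Subgroups are
  assigned from the baseline-window classification. A responder has an SBP
  reduction of at least 5 mm Hg (the threshold below which cardiovascular
  benefit is established).
* Changes are tested with a two-tailed paired Student t test with 95% CIs;
  category-proportion changes with the McNemar test on the paired
  dichotomized classifications (uncorrected chi-square by default, two-tailed
  exact binomial optionally).
* Percentages are reported to 1 decimal (2 decimals for the check-in follow
  rate elsewhere); "moved into lower categories" percentages to the nearest
  integer. Internal computation stays at full precision.

Participants lacking a baseline or follow-up window are excluded from that
horizon's analyses (completer populations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import BPCategory, ValidationError, classify_bp

CATEGORY_ORDER = [BPCategory.CONTROLLED, BPCategory.STAGE1, BPCategory.STAGE2]


# ---------------------------------------------------------------------------
# Windowed means
# ---------------------------------------------------------------------------


def followup_weeks(anchor_week: int) -> Tuple[int, int, int]:
    return (anchor_week - 1, anchor_week, anchor_week + 1)


def window_mean_bp(
    sessions: pd.DataFrame,
    weeks: Sequence[int],
    participant_id: Optional[str] = None,
) -> Optional[Tuple[float, float]]:
    """Unweighted mean of session means over the included weeks, or None.

    ``sessions`` is a tidy frame with participant_id / week / mean_sbp /
    mean_dbp columns.
    """
    df = sessions
    if participant_id is not None:
        df = df[df["participant_id"] == participant_id]
    df = df[df["week"].isin(list(weeks))]
    if len(df) == 0:
        return None
    return float(df["mean_sbp"].mean()), float(df["mean_dbp"].mean())


# ---------------------------------------------------------------------------
# Paired t test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTResult:
    n: int
    mean: float
    sd: float
    ci95: Tuple[float, float]
    t: float
    df: int
    p: float


def paired_t(changes: Sequence[float]) -> PairedTResult:
    """Textbook two-tailed paired Student t test on per-participant deltas.

    t = mean / (sd / sqrt(n)), df = n - 1, CI from the t distribution.
    Zero sd with nonzero mean yields t = +/-inf and p = 0.
    """
    x = np.asarray(list(changes), dtype=float)
    if x.size < 2:
        raise ValidationError("paired t test needs n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("deltas must be finite")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(n, 0.0, 0.0, (0.0, 0.0), 0.0, df, 1.0)
        t = math.inf if mean > 0 else -math.inf
        return PairedTResult(n, mean, 0.0, (mean, mean), t, df, 0.0)
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return PairedTResult(n, mean, sd, (mean - tcrit * se, mean + tcrit * se), t, df, p)


# ---------------------------------------------------------------------------
# McNemar test
# ---------------------------------------------------------------------------


def mcnemar(b: int, c: int, exact: bool = False) -> Tuple[float, float]:
    """McNemar test from the discordant-pair counts.

    ``b`` counts pairs leaving the category, ``c`` pairs entering it. Default
    is the uncorrected chi-square (b-c)^2/(b+c) with 1 df; ``exact`` uses the
    two-tailed binomial(min(b,c); b+c, 1/2) form. b + c = 0 gives (0, 1).
    """
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 0.0, 1.0
    if exact:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return float(min(b, c)), p
    chi2 = (b - c) ** 2 / n
    return float(chi2), float(stats.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# Change table
# ---------------------------------------------------------------------------


def _paired_windows(
    sessions: pd.DataFrame, anchor_week: int
) -> pd.DataFrame:
    """Participants with both baseline (week 1) and follow-up windows."""
    rows = []
    for pid, grp in sessions.groupby("participant_id", sort=True):
        base = window_mean_bp(grp, [1])
        follow = window_mean_bp(grp, followup_weeks(anchor_week))
        if base is None or follow is None:
            continue
        rows.append({
            "participant_id": pid,
            "base_sbp": base[0], "base_dbp": base[1],
            "follow_sbp": follow[0], "follow_dbp": follow[1],
            "base_cat": classify_bp(base[0], base[1]).value,
            "follow_cat": classify_bp(follow[0], follow[1]).value,
        })
    return pd.DataFrame(rows)


def change_table(
    sessions: pd.DataFrame,
    anchor_week: int,
    responder_threshold: float = 5.0,
) -> pd.DataFrame:
    """BP change by baseline subgroup with paired t statistics.

    Returns one row per (measure in SBP/DBP) x (overall + 3 baseline
    categories): n, mean change, SD, 95% CI, t, df, p, and — for SBP — the
    count and percentage of responders (baseline - follow-up SBP >= threshold,
    inclusive). Empty subgroups keep their row with n = 0 and statistics NaN.
    """
    paired = _paired_windows(sessions, anchor_week)
    total = len(paired)
    out = []
    for measure in ("sbp", "dbp"):
        for subgroup in ["overall"] + [c.value for c in CATEGORY_ORDER]:
            sub = paired if subgroup == "overall" else paired[paired["base_cat"] == subgroup] if total else paired
            n = len(sub)
            row: Dict[str, object] = {
                "measure": measure.upper(), "subgroup": subgroup, "n": n,
                "pct_of_total": round(100.0 * n / total, 1) if total else np.nan,
                "mean_change": np.nan, "sd": np.nan, "ci_lo": np.nan,
                "ci_hi": np.nan, "t": np.nan, "df": np.nan, "p": np.nan,
                "responder_n": np.nan, "responder_pct": np.nan,
            }
            if n >= 1:
                deltas = (sub[f"follow_{measure}"] - sub[f"base_{measure}"]).to_numpy()
                row["mean_change"] = float(deltas.mean())
                if n >= 2:
                    res = paired_t(deltas)
                    row.update(sd=res.sd, ci_lo=res.ci95[0], ci_hi=res.ci95[1],
                               t=res.t, df=res.df, p=res.p)
                if measure == "sbp":
                    resp = int(((sub["base_sbp"] - sub["follow_sbp"]) >= responder_threshold).sum())
                    row["responder_n"] = resp
                    row["responder_pct"] = round(100.0 * resp / n, 1)
            out.append(row)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Transition table
# ---------------------------------------------------------------------------


@dataclass
class TransitionResult:
    table: pd.DataFrame
    n: int
    stage2_baseline_n: int
    stage2_moved_down_n: int
    stage2_moved_down_pct: Optional[int]   # nearest integer, None if no stage-2
    excluded_n: int


def transition_table(
    sessions: pd.DataFrame,
    anchor_week: int,
    exact: bool = False,
) -> TransitionResult:
    """Category membership change from baseline to the anchor window.

    Each category is dichotomized (in-category vs not) over the paired
    classifications and fed to the McNemar test. Also reports how many
    stage-2-at-baseline participants moved into lower categories.
    Participants without both windows are excluded (count reported).
    """
    all_ids = sessions["participant_id"].nunique()
    paired = _paired_windows(sessions, anchor_week)
    n = len(paired)
    rows = []
    for cat in CATEGORY_ORDER:
        in_base = paired["base_cat"] == cat.value if n else pd.Series(dtype=bool)
        in_follow = paired["follow_cat"] == cat.value if n else pd.Series(dtype=bool)
        nb, nf = int(in_base.sum()), int(in_follow.sum())
        b = int((in_base & ~in_follow).sum())   # left the category
        c = int((~in_base & in_follow).sum())   # entered the category
        stat, p = mcnemar(b, c, exact=exact)
        rows.append({
            "category": cat.value,
            "n_baseline": nb,
            "pct_baseline": round(100.0 * nb / n, 1) if n else np.nan,
            "n_followup": nf,
            "pct_followup": round(100.0 * nf / n, 1) if n else np.nan,
            "diff_n": nf - nb,
            "diff_pct": round(100.0 * (nf - nb) / n, 1) if n else np.nan,
            "b_discordant": b,
            "c_discordant": c,
            "mcnemar_stat": stat,
            "p": p,
        })
    if n:
        s2 = paired[paired["base_cat"] == BPCategory.STAGE2.value]
        moved = int((s2["follow_cat"] != BPCategory.STAGE2.value).sum())
        pct = round(100.0 * moved / len(s2)) if len(s2) else None
    else:
        s2, moved, pct = paired, 0, None
    return TransitionResult(
        table=pd.DataFrame(rows),
        n=n,
        stage2_baseline_n=len(s2) if n else 0,
        stage2_moved_down_n=moved,
        stage2_moved_down_pct=pct,
        excluded_n=all_ids - n,
    )


# ---------------------------------------------------------------------------
# Engagement
# ---------------------------------------------------------------------------


def engagement_weekly(
    bp_weeks: pd.DataFrame,
    wearable_weeks: pd.DataFrame,
    questionnaire_weeks: pd.DataFrame,
    last_active_week: Dict[str, int],
    n_weeks: int,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Weekly per-task completion and overall engagement rates.

    Inputs are tidy frames with participant_id / week columns (one row per
    record). A participant is active in week w while w <= their last active
    week; a week's task rate is the percentage of active participants with at
    least one record of that task; engaged requires all three tasks. Weeks
    with no active participants are skipped.
    """
    def _week_sets(df: pd.DataFrame) -> Dict[int, set]:
        out: Dict[int, set] = {}
        for pid, wk in zip(df["participant_id"], df["week"]):
            out.setdefault(int(wk), set()).add(pid)
        return out

    bp_w, wear_w, quest_w = map(_week_sets, (bp_weeks, wearable_weeks, questionnaire_weeks))
    rows = []
    for week in range(1, n_weeks + 1):
        active = {p for p, lw in last_active_week.items() if lw >= week}
        if not active:
            continue
        did_bp = active & bp_w.get(week, set())
        did_wear = active & wear_w.get(week, set())
        did_quest = active & quest_w.get(week, set())
        engaged = did_bp & did_wear & did_quest
        na = len(active)
        rows.append({
            "week": week, "n_active": na,
            "bp_pct": round(100.0 * len(did_bp) / na, 1),
            "wearable_pct": round(100.0 * len(did_wear) / na, 1),
            "questionnaire_pct": round(100.0 * len(did_quest) / na, 1),
            "engaged_pct": round(100.0 * len(engaged) / na, 1),
        })
    weekly = pd.DataFrame(rows)
    summary: Dict[str, float] = {}
    for col in ("bp_pct", "wearable_pct", "questionnaire_pct", "engaged_pct"):
        if len(weekly):
            summary[f"{col}_mean"] = round(float(weekly[col].mean()), 1)
            summary[f"{col}_sd"] = round(float(weekly[col].std(ddof=1)), 1) if len(weekly) > 1 else 0.0
    return weekly, summary


# ---------------------------------------------------------------------------
# Cohort flow
# ---------------------------------------------------------------------------


def cohort_flow(
    onboarded: int,
    withdraw_weeks: Iterable[int],
    boundary_week: int = 12,
    final_week: int = 24,
    contacted: Optional[int] = None,
    consented: Optional[int] = None,
) -> Dict[str, float]:
    """Participant funnel: onboarding rate and phase dropout rates (1 decimal).

    Early dropout = withdrawals in weeks 1..boundary over the onboarded count;
    late dropout = withdrawals in (boundary, final] over the completers at the
    boundary.
    """
    weeks = [int(w) for w in withdraw_weeks if w is not None and not pd.isna(w)]
    if any(w < 1 for w in weeks):
        raise ValidationError("withdrawal before onboarding")
    early = sum(1 for w in weeks if w <= boundary_week)
    completers_mid = onboarded - early
    late = sum(1 for w in weeks if boundary_week < w <= final_week)
    completers_final = completers_mid - late
    out: Dict[str, float] = {
        "onboarded": onboarded,
        "withdrawn_early_n": early,
        "dropout_early_pct": round(100.0 * early / onboarded, 1) if onboarded else 0.0,
        "completers_mid": completers_mid,
        "withdrawn_late_n": late,
        "dropout_late_pct": round(100.0 * late / completers_mid, 1) if completers_mid else 0.0,
        "completers_final": completers_final,
    }
    if contacted is not None:
        out["contacted"] = contacted
    if consented is not None:
        out["consented"] = consented
        out["onboard_rate_pct"] = round(100.0 * onboarded / consented, 1) if consented else 0.0
        if contacted:
            out["consent_rate_pct"] = round(100.0 * consented / contacted, 1)
    return out
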