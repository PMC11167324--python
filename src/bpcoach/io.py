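"""CSV schemas and readers/writers for the data and event-log streams.

All files are UTF-8 CSV with a header row and ISO-8601 timestamps; blank cells
mean missing (no sentinel numerics).
"""

from __future__ import annotations

import pandas as pd

BP_SESSION_COLUMNS = [
    "participant_id", "timestamp", "slot",
    "sbp1", "dbp1", "sbp2", "dbp2", "sbp3", "dbp3",
]
LIFESTYLE_COLUMNS = [
    "participant_id", "date", "steps", "active_minutes", "walk_run_speed",
    "sleep_duration", "bedtime", "uptime", "deep_min", "light_min", "rem_min",
    "awake_min", "resting_hr",
]
QUESTIONNAIRE_COLUMNS = [
    "participant_id", "date", "stress", "mood", "alcohol_servings",
    "red_meat_servings", "fruit_veg_servings", "salt_level",
]


def _require(df: pd.DataFrame, columns: list[str], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_bp_sessions(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require(df, BP_SESSION_COLUMNS, str(path))
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_lifestyle(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require(df, LIFESTYLE_COLUMNS, str(path))
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_questionnaire(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require(df, QUESTIONNAIRE_COLUMNS, str(path))
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_truth(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    df["onboard_date"] = pd.to_datetime(df["onboard_date"]).dt.date
    return df


def write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def session_means(bp: pd.DataFrame) -> pd.DataFrame:
    """Per-session mean SBP/DBP over the available (1-3) readings."""
    out = bp[["participant_id", "timestamp", "slot"]].copy()
    if not pd.api.types.is_datetime64_any_dtype(out["timestamp"]):
        out["timestamp"] = pd.to_datetime(out["timestamp"])
    out["mean_sbp"] = bp[["sbp1", "sbp2", "sbp3"]].mean(axis=1, skipna=True)
    out["mean_dbp"] = bp[["dbp1", "dbp2", "dbp3"]].mean(axis=1, skipna=True)
    out["date"] = out["timestamp"].dt.date
    return out


def add_week(df: pd.DataFrame, onboard: "dict[str, object]",
             when: str = "date") -> pd.DataFrame:
    """Attach the participant-anchored week index (column ``week``)."""
    import datetime as _dt

    df = df.copy()
    week = []
    for d, p in zip(df[when], df["participant_id"]):
        if isinstance(d, str):
            dd = _dt.date.fromisoformat(d[:10])
        else:
            dd = d.date() if hasattr(d, "hour") else d
        week.append((dd - onboard[p]).days // 7 + 1)
    df["week"] = week
    return df
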