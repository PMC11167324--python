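"""Per-participant lifestyle -> BP models and factor-impact ranking.

Each participant's BP sessions are paired with lifestyle features aggregated
over a trailing window that ends strictly before the session (wearable
features: mean of the prior ``window`` days; questionnaire items: the entry
from the previous day, i.e. the most recent answer covering the prior 24 h).
Features are standardized within participant, a ridge regression maps them to
session-mean SBP and DBP, and factors are ranked by permutation importance on
the SBP predictions. Ridge is used for determinism and small-n robustness;
the impact metric is model-agnostic so other regressors can be substituted.

Scores are reported on the mm Hg per 1 SD scale: for a linear model with
(near-)orthonormal standardized features, permuting feature j inflates the
mean squared error by about 2*beta_j**2, so sqrt(delta_mse / 2) recovers
|beta_j|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .core_types import (
    LIFESTYLE_FACTORS,
    QUESTIONNAIRE_FACTORS,
    WEARABLE_FACTORS,
    ValidationError,
)

N_WEARABLE = len(WEARABLE_FACTORS)


class ColdStartError(RuntimeError):
    """Raised when a participant has too few aligned rows to fit a model.

    Callers fall back to the generic-recommendation rotation.
    """


@dataclass
class AlignedDataset:
    """Time-aligned feature/label rows for one participant.

    ``X`` holds standardized features (NaN = missing); every row's features
    come strictly from before its label's session time. ``means``/``sds`` are
    the per-participant standardization statistics on the raw scale;
    constant (or never-observed) columns are flagged and carry z = NaN.
    """

    participant_id: str
    X: np.ndarray
    y_sbp: np.ndarray
    y_dbp: np.ndarray
    day_index: np.ndarray
    feature_names: Tuple[str, ...] = LIFESTYLE_FACTORS
    means: np.ndarray = field(default_factory=lambda: np.array([]))
    sds: np.ndarray = field(default_factory=lambda: np.array([]))
    constant_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_rows(self) -> int:
        return int(self.X.shape[0])

    @property
    def insufficient(self) -> bool:
        return self.n_rows == 0


@dataclass
class PersonalModel:
    """A fitted per-participant ridge predictor on standardized features."""

    participant_id: str
    feature_names: Tuple[str, ...]
    coef_sbp: np.ndarray
    coef_dbp: np.ndarray
    intercept_sbp: float
    intercept_dbp: float
    alpha: float
    n_rows: int

    def predict(self, Xz: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Predict (SBP, DBP) from standardized, imputed features."""
        X = np.nan_to_num(np.asarray(Xz, dtype=float), nan=0.0)
        return (X @ self.coef_sbp + self.intercept_sbp,
                X @ self.coef_dbp + self.intercept_dbp)


@dataclass(frozen=True)
class FactorImpact:
    factor: str
    score: float
    direction: int
    rank: int


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------


def build_dataset_arrays(
    participant_id: str,
    factor_matrix: np.ndarray,
    sessions: Sequence[Tuple[int, float, float]],
    window: int = 1,
) -> AlignedDataset:
    """Build an aligned dataset from a dense day-by-factor matrix.

    ``factor_matrix`` has one row per study day (row 0 = day 1) and one column
    per factor in ``LIFESTYLE_FACTORS`` order, NaN where unrecorded.
    ``sessions`` are (day, mean_sbp, mean_dbp) tuples, 1-based days.
    """
    if window < 1:
        raise ValidationError("window must be >= 1 day")
    F = np.asarray(factor_matrix, dtype=float)
    rows, sbp, dbp, days = [], [], [], []
    for day, s, d in sorted(sessions, key=lambda t: t[0]):
        lo, hi = max(0, day - 1 - window), day - 1  # rows strictly before day
        if hi <= lo:
            continue  # no prior days exist
        feats = np.full(len(LIFESTYLE_FACTORS), np.nan)
        wear = F[lo:hi, :N_WEARABLE]
        has = ~np.all(np.isnan(wear), axis=0)
        if has.any():
            feats[np.flatnonzero(has)] = np.nanmean(wear[:, has], axis=0)
        feats[N_WEARABLE:] = F[day - 2, N_WEARABLE:]  # previous-day answers
        if np.all(np.isnan(feats)):
            continue
        rows.append(feats)
        sbp.append(s)
        dbp.append(d)
        days.append(day)

    X = np.asarray(rows, dtype=float).reshape(len(rows), len(LIFESTYLE_FACTORS))
    means = np.full(X.shape[1], np.nan)
    sds = np.full(X.shape[1], np.nan)
    const = np.ones(X.shape[1], dtype=bool)
    if len(rows):
        observed = ~np.all(np.isnan(X), axis=0)
        obs_idx = np.flatnonzero(observed)
        means[obs_idx] = np.nanmean(X[:, obs_idx], axis=0)
        sds[obs_idx] = np.nanstd(X[:, obs_idx], axis=0)
        const = (~observed) | (sds <= 1e-12) | ~np.isfinite(sds)
        Z = np.full_like(X, np.nan)
        ok = ~const
        Z[:, ok] = (X[:, ok] - means[ok]) / sds[ok]
        X = Z
    return AlignedDataset(
        participant_id=participant_id,
        X=X,
        y_sbp=np.asarray(sbp, dtype=float),
        y_dbp=np.asarray(dbp, dtype=float),
        day_index=np.asarray(days, dtype=int),
        means=means,
        sds=sds,
        constant_mask=const,
    )


def build_dataset(
    sessions: pd.DataFrame,
    lifestyle: pd.DataFrame,
    questionnaire: pd.DataFrame,
    window: int = 1,
    participant_id: Optional[str] = None,
) -> AlignedDataset:
    """Build an aligned dataset for one participant from the CSV-schema frames.

    ``sessions`` needs participant_id/timestamp plus either mean_sbp/mean_dbp
    or the raw reading columns. Frames may contain several participants, in
    which case ``participant_id`` selects one.
    """
    from .io import session_means

    if participant_id is None:
        ids = set(sessions["participant_id"])
        if len(ids) != 1:
            raise ValidationError("participant_id required for multi-participant frames")
        participant_id = next(iter(ids))
    sess = sessions[sessions["participant_id"] == participant_id]
    if "mean_sbp" not in sess.columns:
        sess = session_means(sess)
    life = lifestyle[lifestyle["participant_id"] == participant_id]
    quest = questionnaire[questionnaire["participant_id"] == participant_id]
    if len(sess) == 0:
        raise ValidationError("at least one BP session is required")

    def _day_of(ts):
        return ts.date() if hasattr(ts, "hour") else ts

    dates = [_day_of(t) for t in sess["timestamp"]]
    all_dates = list(dates) + [d for d in life["date"]] + [d for d in quest["date"]]
    day0 = min(all_dates)
    n_days = max((_day_of(t) - day0).days for t in all_dates) + 1
    F = np.full((n_days, len(LIFESTYLE_FACTORS)), np.nan)
    for _, row in life.iterrows():
        r = (row["date"] - day0).days
        for j, f in enumerate(WEARABLE_FACTORS):
            v = row.get(f)
            if v is not None and pd.notna(v):
                F[r, j] = float(v)
    for _, row in quest.iterrows():
        r = (row["date"] - day0).days
        for j, f in enumerate(QUESTIONNAIRE_FACTORS):
            v = row.get(f)
            if v is not None and pd.notna(v):
                F[r, N_WEARABLE + j] = float(v)
    triples = [
        ((d - day0).days + 1, s, b)
        for d, s, b in zip(dates, sess["mean_sbp"], sess["mean_dbp"])
    ]
    return build_dataset_arrays(participant_id, F, triples, window=window)


# ---------------------------------------------------------------------------
# Model fitting and ranking
# ---------------------------------------------------------------------------


def fit_personal_model(
    data: AlignedDataset,
    min_rows: int = 14,
    alpha: float = 1.0,
) -> PersonalModel:
    """Fit the per-participant ridge predictor.

    Missing standardized features are mean-imputed (zero). Raises
    :class:`ColdStartError` below ``min_rows`` aligned rows.
    """
    if data.n_rows < min_rows:
        raise ColdStartError(
            f"{data.participant_id}: {data.n_rows} rows < min_rows={min_rows}"
        )
    X = np.nan_to_num(data.X, nan=0.0)
    y = np.column_stack([data.y_sbp, data.y_dbp])
    model = Ridge(alpha=alpha)
    model.fit(X, y)
    return PersonalModel(
        participant_id=data.participant_id,
        feature_names=data.feature_names,
        coef_sbp=model.coef_[0].copy(),
        coef_dbp=model.coef_[1].copy(),
        intercept_sbp=float(model.intercept_[0]),
        intercept_dbp=float(model.intercept_[1]),
        alpha=alpha,
        n_rows=data.n_rows,
    )


def rank_factor_impact(
    model: PersonalModel,
    data: AlignedDataset,
    repeats: int = 20,
    seed: int = 0,
) -> List[FactorImpact]:
    """Rank lifestyle factors by permutation importance on SBP predictions.

    For each factor, its standardized column is shuffled ``repeats`` times and
    the mean MSE inflation converted to a mm Hg / SD magnitude. SBP is the
    primary score; the DBP magnitude breaks ties, then factor name
    (alphabetical). Constant columns score 0. Each factor's permutation
    stream is keyed by the factor name, so the ranking is invariant to the
    column order of the dataset.
    """
    import zlib

    X = np.nan_to_num(data.X, nan=0.0)
    n = X.shape[0]
    pred_s, pred_d = model.predict(X)
    base_s = float(np.mean((pred_s - data.y_sbp) ** 2))
    base_d = float(np.mean((pred_d - data.y_dbp) ** 2))

    scores_s = np.zeros(X.shape[1])
    scores_d = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if data.constant_mask.size and data.constant_mask[j]:
            continue
        rng = np.random.default_rng(
            [seed, zlib.crc32(data.feature_names[j].encode())]
        )
        inc_s = 0.0
        inc_d = 0.0
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            ps, pd_ = model.predict(Xp)
            inc_s += np.mean((ps - data.y_sbp) ** 2) - base_s
            inc_d += np.mean((pd_ - data.y_dbp) ** 2) - base_d
        scores_s[j] = np.sqrt(max(inc_s / repeats, 0.0) / 2.0)
        scores_d[j] = np.sqrt(max(inc_d / repeats, 0.0) / 2.0)

    order = sorted(
        range(X.shape[1]),
        key=lambda j: (-scores_s[j], -scores_d[j], data.feature_names[j]),
    )
    impacts = []
    for rank, j in enumerate(order, start=1):
        direction = int(np.sign(model.coef_sbp[j])) or +1
        impacts.append(
            FactorImpact(
                factor=data.feature_names[j],
                score=float(scores_s[j]),
                direction=direction,
                rank=rank,
            )
        )
    return impacts


def single_factor_ols_ranking(data: AlignedDataset) -> List[str]:
    """Brute-force oracle: rank factors by |slope| of single-factor OLS fits.

    For each standardized factor, the label (session SBP) is regressed on that
    factor alone over the rows where it is observed; factors are ordered by
    descending absolute slope. Used as an independent benchmark for
    :func:`rank_factor_impact`.
    """
    slopes = []
    for j, name in enumerate(data.feature_names):
        x = data.X[:, j]
        ok = ~np.isnan(x)
        if ok.sum() < 3 or np.nanstd(x[ok]) <= 1e-12:
            slopes.append((0.0, name))
            continue
        xv = x[ok] - x[ok].mean()
        yv = data.y_sbp[ok] - data.y_sbp[ok].mean()
        slopes.append((abs(float(xv @ yv) / float(xv @ xv)), name))
    return [name for _, name in sorted(slopes, key=lambda t: (-t[0], t[1]))]
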