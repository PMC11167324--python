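"""Aligned datasets, ridge fitting, and factor-impact ranking."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from bpcoach.core_types import LIFESTYLE_FACTORS
from bpcoach.personal_model import (
    AlignedDataset,
    ColdStartError,
    build_dataset,
    build_dataset_arrays,
    fit_personal_model,
    rank_factor_impact,
    single_factor_ols_ranking,
)

N_F = len(LIFESTYLE_FACTORS)
STEPS = LIFESTYLE_FACTORS.index("steps")


def _matrix(n_days, fill=np.nan):
    return np.full((n_days, N_F), fill, dtype=float)


def _dataset_from_steps(steps_by_day, session_days, labels, window=1):
    F = _matrix(max([*session_days, *steps_by_day]) + 1)
    for day, v in steps_by_day.items():
        F[day - 1, STEPS] = v
    sessions = [(d, y, y * 0.6) for d, y in zip(session_days, labels)]
    return build_dataset_arrays("p", F, sessions, window=window)


class TestBuildDataset:
    def test_trailing_window_uses_previous_day(self):
        # sessions on days 9 and 10; steps present on days 8 and 9
        data = _dataset_from_steps({8: 4000.0, 9: 9000.0}, [9, 10], [130.0, 120.0])
        raw = data.means[STEPS] + data.X[:, STEPS] * data.sds[STEPS]
        assert raw == pytest.approx([4000.0, 9000.0])

    def test_session_without_prior_data_dropped(self):
        data = _dataset_from_steps({9: 9000.0}, [1, 10], [130.0, 120.0])
        assert data.n_rows == 1 and data.day_index.tolist() == [10]

    def test_no_usable_rows_signalled_not_raised(self):
        data = build_dataset_arrays("p", _matrix(10), [(5, 130.0, 80.0)])
        assert data.insufficient and data.n_rows == 0

    def test_wider_window_averages(self):
        data = _dataset_from_steps({6: 4000.0, 7: 8000.0}, [8], [130.0], window=2)
        raw = data.means[STEPS]  # single row: mean equals the aggregate
        assert raw == pytest.approx(6000.0)

    def test_no_temporal_leakage(self):
        base = _dataset_from_steps({8: 4000.0, 9: 9000.0, 14: 100.0},
                                   [9, 10], [130.0, 120.0])
        shuffled = _dataset_from_steps({8: 4000.0, 9: 9000.0, 14: 99999.0},
                                       [9, 10], [130.0, 120.0])
        np.testing.assert_allclose(base.X, shuffled.X)

    def test_dataframe_interface_matches_schema(self):
        sessions = pd.DataFrame({
            "participant_id": ["p"] * 2,
            "timestamp": pd.to_datetime(["2022-01-10 08:00", "2022-01-11 08:00"]),
            "mean_sbp": [130.0, 126.0], "mean_dbp": [84.0, 80.0],
        })
        lifestyle = pd.DataFrame({
            "participant_id": ["p"] * 2,
            "date": [dt.date(2022, 1, 9), dt.date(2022, 1, 10)],
            "steps": [7000, 9000], "active_minutes": [30, 40],
            "sleep_duration": [400, 420], "resting_hr": [66, 64],
        })
        quest = pd.DataFrame({
            "participant_id": ["p"],
            "date": [dt.date(2022, 1, 9)],
            "stress": [3], "mood": [4], "alcohol_servings": [0],
            "red_meat_servings": [1], "fruit_veg_servings": [2], "salt_level": [3],
        })
        data = build_dataset(sessions, lifestyle, quest)
        assert data.n_rows == 2
        raw_steps = data.means[STEPS] + data.X[:, STEPS] * data.sds[STEPS]
        assert raw_steps == pytest.approx([7000.0, 9000.0])


class TestFit:
    def test_noiseless_recovery_in_small_penalty_limit(self):
        rng = np.random.default_rng(3)
        n = 50
        steps = rng.normal(8000, 3000, n)
        F = _matrix(n + 1)
        for i, v in enumerate(steps):
            F[i, STEPS] = v
        sessions = []
        for day in range(2, n + 2):
            z = (steps[day - 2] - steps.mean()) / steps.std()
            y = 120 + 5 * z
            sessions.append((day, y, 0.6 * y))
        data = build_dataset_arrays("p", F, sessions)
        model = fit_personal_model(data, alpha=1e-8)
        assert model.coef_sbp[STEPS] == pytest.approx(5.0, abs=1e-6)

    def test_constant_labels_give_zero_coefficients(self):
        rng = np.random.default_rng(4)
        F = _matrix(40)
        F[:, STEPS] = rng.normal(8000, 3000, 40)
        data = build_dataset_arrays("p", F, [(d, 125.0, 80.0) for d in range(2, 40)])
        model = fit_personal_model(data)
        assert np.allclose(model.coef_sbp, 0.0, atol=1e-8)
        assert model.intercept_sbp == pytest.approx(125.0)

    def test_cold_start_below_min_rows(self):
        data = _dataset_from_steps({8: 4000.0}, [9], [130.0])
        with pytest.raises(ColdStartError):
            fit_personal_model(data, min_rows=14)

    def test_two_factor_effect_ratio_recovered(self):
        rng = np.random.default_rng(7)
        n = 100
        F = _matrix(n + 1)
        salt = LIFESTYLE_FACTORS.index("salt_level")
        F[:, STEPS] = rng.normal(8000, 3000, n + 1)
        F[:, salt] = rng.normal(3, 1.1, n + 1)
        sessions = []
        zs = (F[:, STEPS] - np.nanmean(F[:, STEPS])) / np.nanstd(F[:, STEPS])
        zl = (F[:, salt] - np.nanmean(F[:, salt])) / np.nanstd(F[:, salt])
        for day in range(2, n + 2):
            y = 130 - 10 * zs[day - 2] + 1 * zl[day - 2] + rng.normal(0, 1)
            sessions.append((day, y, 0.6 * y))
        data = build_dataset_arrays("p", F, sessions)
        model = fit_personal_model(data, alpha=1e-6)
        ratio = abs(model.coef_sbp[STEPS]) / abs(model.coef_sbp[salt])
        assert 5 <= ratio <= 20


class TestRanking:
    def _noisy_dataset(self, informative="salt_level", coef=4.0, n=80, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, N_F))
        j = LIFESTYLE_FACTORS.index(informative)
        y = 130 + coef * X[:, j] + rng.normal(0, 1, n)
        return AlignedDataset(
            participant_id="p", X=X, y_sbp=y, y_dbp=0.6 * y,
            day_index=np.arange(2, n + 2),
            means=np.zeros(N_F), sds=np.ones(N_F),
            constant_mask=np.zeros(N_F, dtype=bool),
        )

    def test_single_informative_factor_ranks_first(self):
        data = self._noisy_dataset()
        model = fit_personal_model(data)
        ranking = rank_factor_impact(model, data, seed=1)
        assert ranking[0].factor == "salt_level"
        assert ranking[0].rank == 1
        assert ranking[0].direction == +1
        assert [fi.rank for fi in ranking] == list(range(1, N_F + 1))

    def test_scores_sorted_nonincreasing(self):
        data = self._noisy_dataset()
        model = fit_personal_model(data)
        scores = [fi.score for fi in rank_factor_impact(model, data, seed=1)]
        assert scores == sorted(scores, reverse=True)

    def test_deterministic_given_seed(self):
        data = self._noisy_dataset(seed=5)
        model = fit_personal_model(data)
        a = rank_factor_impact(model, data, seed=9)
        b = rank_factor_impact(model, data, seed=9)
        assert a == b

    def test_column_order_permutation_leaves_ranking_unchanged(self):
        data = self._noisy_dataset(seed=2)
        model = fit_personal_model(data)
        perm = np.random.default_rng(0).permutation(N_F)
        permuted = AlignedDataset(
            participant_id="p", X=data.X[:, perm], y_sbp=data.y_sbp,
            y_dbp=data.y_dbp, day_index=data.day_index,
            feature_names=tuple(LIFESTYLE_FACTORS[j] for j in perm),
            means=data.means[perm], sds=data.sds[perm],
            constant_mask=data.constant_mask[perm],
        )
        model_p = fit_personal_model(permuted)
        order_a = [fi.factor for fi in rank_factor_impact(model, data, seed=3)]
        order_b = [fi.factor for fi in rank_factor_impact(model_p, permuted, seed=3)]
        assert order_a == order_b

    def test_constant_column_scores_zero(self):
        data = self._noisy_dataset(seed=6)
        data.X[:, 0] = np.nan
        data.constant_mask[0] = True
        model = fit_personal_model(data)
        ranking = rank_factor_impact(model, data, seed=1)
        const_entry = next(fi for fi in ranking if fi.factor == LIFESTYLE_FACTORS[0])
        assert const_entry.score == 0.0

    def test_permutation_score_approximates_planted_magnitude(self):
        data = self._noisy_dataset(coef=4.0, n=400, seed=8)
        model = fit_personal_model(data, alpha=1e-6)
        top = rank_factor_impact(model, data, seed=1)[0]
        assert top.score == pytest.approx(4.0, rel=0.2)

    def test_ols_oracle_agrees_on_dominant_signal(self):
        data = self._noisy_dataset(seed=11)
        assert single_factor_ols_ranking(data)[0] == "salt_level"
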