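"""Generator determinism, calibration, and planted-structure recovery."""

import numpy as np
import pandas as pd
import pytest

from bpcoach.coach import DEFAULT_CATALOG
from bpcoach.core_types import BPCategory, LIFESTYLE_FACTORS, ValidationError
from bpcoach.io import add_week, session_means
from bpcoach.synthetic_cohort import (
    CohortConfig,
    calibrate_follow_intercept,
    follow_probability,
    generate_cohort,
    phase_hazard,
    simulate_dropout,
    simulate_response,
    _draw_truth,
)


def _fast_config(**kw):
    base = dict(n_participants=6, weeks=6, seed=21)
    base.update(kw)
    return CohortConfig(**base)


class TestConfigValidation:
    def test_bad_mix_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(baseline_mix=(0.5, 0.5, 0.5))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(n_participants=-1)

    def test_zero_weeks_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(weeks=0)


class TestReproducibility:
    def test_identical_config_identical_streams(self):
        a = generate_cohort(_fast_config())
        b = generate_cohort(_fast_config())
        assert a.bp_sessions.to_csv(index=False) == b.bp_sessions.to_csv(index=False)
        assert a.lifestyle_daily.to_csv(index=False) == b.lifestyle_daily.to_csv(index=False)
        assert a.questionnaire_daily.to_csv(index=False) == b.questionnaire_daily.to_csv(index=False)
        assert a.truth_frame().to_csv(index=False) == b.truth_frame().to_csv(index=False)

    def test_adding_participants_preserves_existing_streams(self):
        small = generate_cohort(_fast_config(n_participants=4))
        large = generate_cohort(_fast_config(n_participants=6))
        ids = set(small.bp_sessions["participant_id"])
        big_subset = large.bp_sessions[large.bp_sessions["participant_id"].isin(ids)]
        assert small.bp_sessions.to_csv(index=False) == big_subset.to_csv(index=False)


class TestPlantedStructure:
    def test_category_mix_close_to_config(self):
        cfg = CohortConfig(n_participants=141, weeks=1, seed=7, coaching=False)
        truths = [_draw_truth(cfg, i) for i in range(cfg.n_participants)]
        fracs = {
            cat: sum(t.baseline_category is cat for t in truths) / len(truths)
            for cat in BPCategory
        }
        for cat, planted in zip(BPCategory, cfg.baseline_mix):
            # multinomial SE ~ sqrt(p(1-p)/141) ~ 0.04; allow 3 SEs
            assert abs(fracs[cat] - planted) < 0.12

    def test_planted_baselines_match_observed_week1_means(self):
        cfg = CohortConfig(n_participants=100, weeks=2, seed=13, coaching=False)
        cohort = generate_cohort(cfg)
        truth = cohort.truth_frame()
        onboard = {t.participant_id: t.onboard_date for t in cohort.truths}
        sess = add_week(session_means(cohort.bp_sessions), onboard, when="date")
        wk1 = sess[sess["week"] == 1].groupby("participant_id")["mean_sbp"].mean()
        merged = truth.set_index("participant_id").join(wk1.rename("observed"))
        for cat in ("controlled", "stage1", "stage2"):
            sub = merged[merged["baseline_category"] == cat].dropna(subset=["observed"])
            assert abs(sub["observed"].mean() - sub["baseline_sbp"].mean()) < 2.0

    def test_dominant_factor_visible_at_vanishing_noise(self):
        cfg = CohortConfig(
            n_participants=5, weeks=10, seed=3, coaching=False,
            dominant_factor_mode=True, coef_background=(0.0, 0.0),
            noise_sd=0.01, reading_jitter_sd=0.0,
            weekly_bp_p=1.0, daily_bp_p=1.0, weekly_wear_p=1.0,
            daily_wear_p=1.0, weekly_quest_p=1.0, daily_quest_p=1.0,
            dropout_by_week12=0.0, dropout_12_to_24=0.0, spike_daily_p=0.0,
        )
        cohort = generate_cohort(cfg)
        from bpcoach.engine import _recorded_matrix
        from bpcoach.personal_model import build_dataset_arrays

        life = cohort.lifestyle_daily.copy()
        life["date"] = pd.to_datetime(life["date"]).dt.date
        quest = cohort.questionnaire_daily.copy()
        quest["date"] = pd.to_datetime(quest["date"]).dt.date
        sess = session_means(cohort.bp_sessions)
        for t in cohort.truths:
            F = _recorded_matrix(t, life[life.participant_id == t.participant_id],
                                 quest[quest.participant_id == t.participant_id],
                                 cfg.weeks * 7)
            ps = sess[sess.participant_id == t.participant_id]
            triples = [((ts.date() - t.onboard_date).days + 1, s, d)
                       for ts, s, d in zip(ps.timestamp, ps.mean_sbp, ps.mean_dbp)]
            data = build_dataset_arrays(t.participant_id, F, triples)
            j = LIFESTYLE_FACTORS.index(t.dominant_factor)
            x = data.X[:, j]
            ok = ~np.isnan(x)
            corr = np.corrcoef(x[ok], data.y_sbp[ok])[0, 1]
            assert abs(corr) > 0.9
            assert np.sign(corr) == np.sign(t.coef[t.dominant_factor])

    def test_no_truth_leakage_into_streams(self):
        cohort = generate_cohort(_fast_config())
        truth_cols = {"baseline_sbp", "baseline_dbp", "noise_sd", "follow_intercept",
                      "adherence_slope", "dominant_factor"} | {
                          f"coef_{f}" for f in LIFESTYLE_FACTORS}
        for df in (cohort.bp_sessions, cohort.lifestyle_daily,
                   cohort.questionnaire_daily):
            assert not truth_cols & set(df.columns)


class TestAdherence:
    def _truth(self):
        cfg = CohortConfig(n_participants=1, weeks=1, seed=0, coaching=False)
        return _draw_truth(cfg, 0)

    def test_follow_probability_decreasing(self):
        t = self._truth()
        ps = [follow_probability(d, t.follow_intercept, t.adherence_slope)
              for d in range(1, 6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_marginal_follow_rate_calibrated(self):
        t = self._truth()
        rng = np.random.default_rng(0)
        rec = DEFAULT_CATALOG[0]
        n = 20_000
        followed = 0
        for _ in range(n):
            difficulty = int(rng.integers(1, 6))
            checkin, _ = simulate_response(t, rec, difficulty, rng)
            followed += checkin.followed
        assert followed / n == pytest.approx(0.6364, abs=0.02)

    def test_followed_recommendations_were_easier(self):
        t = self._truth()
        rng = np.random.default_rng(1)
        rec = DEFAULT_CATALOG[0]
        diff_f, diff_n = [], []
        for _ in range(10_000):
            d = int(rng.integers(1, 6))
            checkin, _ = simulate_response(t, rec, d, rng)
            (diff_f if checkin.followed else diff_n).append(d)
        assert np.mean(diff_f) < np.mean(diff_n)

    def test_followed_recommendation_shifts_target_factor(self):
        t = self._truth()
        rng = np.random.default_rng(2)
        rec = DEFAULT_CATALOG[0]
        for _ in range(50):
            checkin, delta = simulate_response(t, rec, 1, rng, step=0.4)
            if checkin.followed:
                assert delta == {rec.factor: 0.4}
                break
        else:
            pytest.fail("difficulty-1 recommendation never followed in 50 draws")

    def test_invalid_difficulty_rejected(self):
        with pytest.raises(ValidationError):
            simulate_response(self._truth(), DEFAULT_CATALOG[0], 0,
                              np.random.default_rng(0))

    def test_intercept_calibration_solves_target(self):
        a = calibrate_follow_intercept(0.6364, 1.0)
        mean_p = np.mean([follow_probability(d, a, 1.0) for d in range(1, 6)])
        assert mean_p == pytest.approx(0.6364, abs=1e-9)


class TestDropout:
    def test_zero_hazard_everyone_completes(self):
        cfg = _fast_config(dropout_by_week12=0.0, dropout_12_to_24=0.0)
        cohort = generate_cohort(cfg)
        assert all(t.withdraw_week is None for t in cohort.truths)

    def test_cumulative_hazard_calibration(self):
        # simulated cumulative dropout by week 12 stays within binomial error
        cfg = CohortConfig(n_participants=1, weeks=1, seed=0, coaching=False)
        truth = _draw_truth(cfg, 0)
        rng = np.random.default_rng(3)
        n_rep, n_pat = 200, 141
        dropped = 0
        for _ in range(n_rep * n_pat):
            for week in range(1, 13):
                if simulate_dropout(truth, week, rng):
                    dropped += 1
                    break
        rate = dropped / (n_rep * n_pat)
        assert rate == pytest.approx(0.092, abs=0.03)

    def test_withdrawn_emit_no_further_data(self):
        cfg = _fast_config(n_participants=20, weeks=8, seed=9,
                           dropout_by_week12=0.6)
        cohort = generate_cohort(cfg)
        onboard = {t.participant_id: t.onboard_date for t in cohort.truths}
        sess = add_week(session_means(cohort.bp_sessions), onboard, when="date")
        withdrawn = [t for t in cohort.truths if t.withdraw_week is not None]
        assert withdrawn, "expected withdrawals under a high hazard"
        for t in withdrawn:
            weeks = sess[sess["participant_id"] == t.participant_id]["week"]
            assert (weeks <= t.withdraw_week).all()
            assert not any(e.week > t.withdraw_week
                           for e in cohort.recommendations
                           if e.participant_id == t.participant_id)

    def test_phase_hazard_inverts_cumulative(self):
        h = phase_hazard(0.092, 12)
        assert 1 - (1 - h) ** 12 == pytest.approx(0.092)


class TestBoundaries:
    def test_empty_cohort_schema_valid(self):
        cohort = generate_cohort(_fast_config(n_participants=0))
        assert len(cohort.bp_sessions) == 0
        assert list(cohort.bp_sessions.columns)[:3] == ["participant_id", "timestamp", "slot"]

    def test_reading_count_always_three(self, small_cohort):
        bp = small_cohort.bp_sessions
        assert bp[["sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3"]].notna().all().all()
        assert (bp[["sbp1", "sbp2", "sbp3"]].to_numpy()
                > bp[["dbp1", "dbp2", "dbp3"]].to_numpy()).all()
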