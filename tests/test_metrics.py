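"""Attention metrics: RT trimming, accuracy, raycast means, preferences."""

import numpy as np
import pandas as pd
import pytest

from vrsearch.geometry import AngularPosition
from vrsearch.metrics import (
    ALL_METRICS,
    POOLED_METRICS,
    PRIMARY_METRICS,
    accuracy_for_level,
    assign_quadrant,
    compute_metric_vector,
    raycast_mean,
    rt_for_level,
    trim_rt_outliers,
)
from vrsearch.model import PlayerSession, TrialRecord
from vrsearch.simulate import AgentParams, simulate_session

from conftest import brute_fences


def _trial(pid, level, idx, target, correct=True, rt=2.0):
    tgt = AngularPosition(*target)
    sel = tgt if correct else AngularPosition(0.0, 0.0) if target != (0.0, 0.0) else AngularPosition(10.0, 0.0)
    return TrialRecord(pid, level, idx, tgt, sel, correct, rt)


class TestRTTrimming:
    def test_zero_iqr_keeps_everything(self):
        trim = trim_rt_outliers([2.0, 2.0, 2.0, 2.0])
        assert trim.keep_mask.all()
        assert trim.fences.lower == trim.fences.upper == 2.0

    def test_extreme_value_flagged(self):
        # type-7 quartiles of [2, 2, 2, 100]: Q3 = 26.5, upper fence 63.25
        trim = trim_rt_outliers([2.0, 2.0, 2.0, 100.0])
        assert trim.fences.q3 == pytest.approx(26.5)
        assert trim.fences.upper == pytest.approx(63.25)
        assert list(trim.keep_mask) == [True, True, True, False]
        assert trim.kept.mean() == pytest.approx(2.0)

    def test_empty_input_is_empty_result(self):
        trim = trim_rt_outliers([])
        assert trim.fences is None and len(trim.kept) == 0

    def test_matches_brute_force_oracle_on_lognormal_draws(self):
        rng = np.random.default_rng(7)
        rts = rng.lognormal(0.5, 0.8, size=200)
        trim = trim_rt_outliers(rts)
        lo, hi = brute_fences(rts)
        expected = (rts < lo) | (rts > hi)
        assert np.array_equal(~trim.keep_mask, expected)

    def test_single_pass_contract(self):
        # trimming is applied once; re-trimming the kept set may flag anew
        # only because fences are recomputed — the first pass never iterates
        rts = np.array([1.0, 1.1, 1.2, 1.3, 5.0])
        trim = trim_rt_outliers(rts)
        assert (~trim.keep_mask).sum() == 1
        # kept values all lie strictly inside the original fences
        assert (trim.kept > trim.fences.lower - 1e-12).all()
        assert (trim.kept < trim.fences.upper + 1e-12).all()


class TestLevelMetrics:
    def test_accuracy_cases(self):
        mk = lambda n, k: [
            _trial("p", "axes", i, (25.0, 0.0), correct=i < k) for i in range(n)
        ]
        assert accuracy_for_level(mk(18, 0)) == 0.0
        assert accuracy_for_level(mk(10, 10)) == 100.0
        assert accuracy_for_level(mk(8, 6)) == 75.0
        assert np.isnan(accuracy_for_level([]))

    def test_rt_mean_and_missingness(self):
        trials = [_trial("p", "axes", i, (25.0, 0.0), rt=r) for i, r in enumerate([1.0, 2.0, 3.0])]
        assert rt_for_level(trials) == pytest.approx(2.0)
        wrong = [_trial("p", "axes", i, (25.0, 0.0), correct=False) for i in range(3)]
        assert np.isnan(rt_for_level(wrong))

    def test_raycast_mean_symmetry_and_phase_filter(self):
        frames = pd.DataFrame(
            {
                "level": "axes",
                "trial_index": 0,
                "time_s": np.arange(6) / 10,
                "phase": ["cue", "cue", "array", "array", "array", "array"],
                "head_lat": [99.0, 99.0, -10.0, 10.0, -10.0, 10.0],
                "head_vert": 0.0,
                "ctrl_lat": 5.0,
                "ctrl_vert": 0.0,
            }
        )
        assert raycast_mean(frames, "headset", "lateral", "axes") == pytest.approx(0.0)
        assert raycast_mean(frames, "controller", "lateral", "axes") == pytest.approx(5.0)
        assert np.isnan(raycast_mean(frames, "headset", "lateral", "depth"))

    def test_raycast_mean_recovers_injected_bias(self, small_game):
        game, _ = small_game
        agent = AgentParams(lateral_bias=20.0, frame_rate=30.0)
        session = simulate_session(agent, game.scaled(10.0), seed=11)
        n_array = (session.frames["phase"] == "array").sum()
        assert n_array > 10_000
        assert raycast_mean(session.frames, "headset", "lateral") == pytest.approx(20.0, abs=1.0)


class TestQuadrantsAndPreferences:
    @pytest.mark.parametrize(
        "pos, expected",
        [
            ((25.0, 0.0), "right"),
            ((0.0, -25.0), "down"),
            ((-30.0, 10.0), "left"),
            ((5.0, 12.0), "up"),
            ((20.0, 20.0), "axis"),
            ((0.0, 0.0), "axis"),
        ],
    )
    def test_dominant_axis_rule(self, pos, expected):
        assert assign_quadrant(AngularPosition(*pos)) == expected

    def test_sign_conventions_from_construction(self):
        # right targets always correct and fast; left targets slow/incorrect
        trials = []
        for i in range(8):
            trials.append(_trial("p", "axes", 2 * i, (25.0, 0.0), correct=True, rt=2.0))
            trials.append(
                _trial("p", "axes", 2 * i + 1, (-25.0, 0.0), correct=(i < 4), rt=4.0)
            )
        session = PlayerSession("p", "patient", trials)
        mv = compute_metric_vector(session)
        assert mv.pooled["acc_lr"] == pytest.approx(50.0)  # 100% − 50%
        assert mv.pooled["rt_lr"] == pytest.approx(2.0)  # 4 s − 2 s

    def test_eccentricity_convention_central_positive(self):
        trials = []
        for i in range(10):
            trials.append(_trial("p", "axes", 2 * i, (12.5, 0.0), correct=True, rt=2.0))
            trials.append(_trial("p", "axes", 2 * i + 1, (25.0, 0.0), correct=(i < 7), rt=3.0))
        mv = compute_metric_vector(PlayerSession("p", "control", trials))
        assert mv.pooled["acc_ecc25"] == pytest.approx(30.0)  # 100 − 70
        assert mv.pooled["rt_ecc25"] == pytest.approx(1.0)  # 3 − 2
        flipped = compute_metric_vector(
            PlayerSession("p", "control", trials), central_positive=False
        )
        assert flipped.pooled["acc_ecc25"] == pytest.approx(-30.0)


class TestMetricVector:
    def test_has_exactly_14_metrics(self, fixture_cohort):
        sessions, _ = fixture_cohort
        mv = compute_metric_vector(sessions[0])
        assert mv.n_metrics == 14
        assert len(PRIMARY_METRICS) + len(POOLED_METRICS) == len(ALL_METRICS) == 14

    def test_empty_session_all_missing_with_warning(self):
        with pytest.warns(UserWarning, match="no analysable levels"):
            mv = compute_metric_vector(PlayerSession("empty", "control"))
        assert mv.per_level.isna().all().all()
        assert all(np.isnan(v) for v in mv.pooled.values())

    def test_fixture_expectations_hold(self, fixture_cohort):
        """Compositional oracle: pipeline values equal hand-computed ones."""
        sessions, expected = fixture_cohort
        vectors = {s.player_id: compute_metric_vector(s) for s in sessions}
        for _, row in expected.iterrows():
            mv = vectors[row["player_id"]]
            got = (
                mv.pooled[row["metric"]]
                if row["level"] == "pooled"
                else mv.per_level.loc[row["level"], row["metric"]]
            )
            if np.isnan(row["value"]):
                assert np.isnan(got), (row["player_id"], row["metric"])
            else:
                assert got == pytest.approx(row["value"]), (row["player_id"], row["metric"])

    def test_accuracy_conservation(self, small_game):
        game, _ = small_game
        session = simulate_session(AgentParams(frame_rate=10), game, seed=3)
        for level in ("axes", "stimuli"):
            trials = session.trials_for_level(level)
            n_corr = sum(t.correct for t in trials)
            n_inc = sum(not t.correct for t in trials)
            assert n_corr + n_inc == len(trials)
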