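"""Generative model: determinism, bookkeeping, and behavioural structure."""

import numpy as np
import pandas as pd
import pytest

from vrsearch.io import sessions_to_tables
from vrsearch.metrics import compute_metric_vector, raycast_mean
from vrsearch.model import default_game
from vrsearch.simulate import (
    AgentParams,
    CohortSpec,
    level_elements,
    simulate_cohort,
    simulate_session,
    simulate_trial,
)


@pytest.fixture(scope="module")
def axes_level():
    return default_game().level("axes")


class TestTrial:
    def test_deterministic_single_inspection_limit(self, axes_level):
        # with zero noise, any trial resolved on the first inspection has
        # RT exactly base_dwell + motor_time and must be correct
        agent = AgentParams(dwell_noise_sd=0.0, orientation_noise_sd=0.0,
                            selection_error_rate=0.0, frame_rate=10)
        rng = np.random.default_rng(0)
        single = []
        for k in range(50):
            trial, _ = simulate_trial(agent, axes_level, rng, trial_index=k)
            if trial.rt == pytest.approx(agent.base_dwell + agent.motor_time):
                single.append(trial)
        assert single, "expected at least one first-inspection trial"
        assert all(t.correct for t in single)

    def test_forced_miss_gives_give_up_distractor_selection(self, axes_level):
        # enormous contralesional deficit: left-hemifield targets cannot be
        # detected, so the agent gives up and selects a distractor
        agent = AgentParams(lateral_bias=10.0, contralesional_miss_slope=1.0,
                            give_up_after=10, frame_rate=10, selection_error_rate=0.0)
        rng = np.random.default_rng(1)
        gave_up = 0
        for k in range(0, 40, 2):  # even indices: horizontal axes trials
            trial, _ = simulate_trial(agent, axes_level, rng, trial_index=k)
            if trial.target_position.lateral <= -12.5:
                assert not trial.correct
                assert trial.selected_position != trial.target_position
                gave_up += 1
        assert gave_up > 0

    def test_frame_count_matches_rt(self, axes_level):
        agent = AgentParams(frame_rate=30)
        rng = np.random.default_rng(2)
        trial, frames = simulate_trial(agent, axes_level, rng)
        n_arr = (frames["phase"] == "array").sum()
        assert abs(n_arr - trial.rt * agent.frame_rate) <= 1

    def test_target_is_among_elements(self, axes_level):
        rng = np.random.default_rng(3)
        trial, _ = simulate_trial(AgentParams(frame_rate=10), axes_level, rng)
        tgt = [trial.target_position.lateral, trial.target_position.vertical]
        assert any(np.allclose(tgt, e) for e in trial.element_positions)


class TestLevelElements:
    def test_axes_trials_alternate_orientation(self, axes_level):
        horiz = level_elements(axes_level, 0)
        vert = level_elements(axes_level, 1)
        assert np.all(horiz[:, 1] == 0) and np.all(vert[:, 0] == 0)
        assert len(horiz) == len(vert) == 8

    def test_ring_levels_have_unambiguous_quadrants(self):
        from vrsearch.geometry import AngularPosition
        from vrsearch.metrics import assign_quadrant

        stim = default_game().level("stimuli")
        els = level_elements(stim, 0)
        quads = {assign_quadrant(AngularPosition(*e)) for e in els}
        assert "axis" not in quads
        assert quads == {"left", "right", "up", "down"}

    def test_full_field_has_four_rings(self):
        ff = default_game().level("full_field")
        els = level_elements(ff, 0)
        assert len(els) == 32
        from vrsearch.geometry import AngularPosition, eccentricity

        eccs = {round(eccentricity(AngularPosition(*e)), 3) for e in els}
        assert eccs == {12.5, 25.0, 37.5, 50.0}


class TestSession:
    def test_same_seed_identical_session(self, small_game):
        game, _ = small_game
        a = simulate_session(AgentParams(frame_rate=10), game, seed=5)
        b = simulate_session(AgentParams(frame_rate=10), game, seed=5)
        ta, fa = sessions_to_tables([a])
        tb, fb = sessions_to_tables([b])
        pd.testing.assert_frame_equal(ta, tb)
        pd.testing.assert_frame_equal(fa, fb)

    def test_levels_respect_min_duration(self, small_game):
        game, _ = small_game
        s = simulate_session(AgentParams(frame_rate=10), game, seed=6)
        for level in game.levels:
            if not level.has_trials:
                continue
            trials = s.trials_for_level(level.name)
            from vrsearch.simulate import CUE_DURATION

            total = sum(CUE_DURATION + t.rt for t in trials)
            assert total >= level.min_duration * 60.0

    def test_unbiased_agent_centred(self, small_game):
        game, _ = small_game
        s = simulate_session(AgentParams(frame_rate=10), game.scaled(4), seed=7)
        assert raycast_mean(s.frames, "headset", "lateral") == pytest.approx(0.0, abs=1.0)

    def test_bias_sign_symmetry(self, small_game):
        game, _ = small_game
        left = simulate_session(AgentParams(lateral_bias=-15, frame_rate=10), game, seed=8)
        right = simulate_session(AgentParams(lateral_bias=15, frame_rate=10), game, seed=8)
        ml = raycast_mean(left.frames, "headset", "lateral")
        mr = raycast_mean(right.frames, "headset", "lateral")
        assert ml == pytest.approx(-mr, abs=1.5)
        assert ml < -5 < 5 < mr

    def test_right_favouring_agent_positive_lr_scores(self, small_game):
        game, _ = small_game
        agent = AgentParams(lateral_bias=20.0, contralesional_miss_slope=0.015,
                            frame_rate=10)
        s = simulate_session(agent, game.scaled(3), seed=9, group="patient")
        mv = compute_metric_vector(s)
        assert mv.pooled["acc_lr"] > 0
        assert mv.pooled["rt_lr"] > 0


class TestCohort:
    def test_empty_cohort(self):
        spec = CohortSpec(n_controls=0, n_patients=0)
        assert simulate_cohort(spec) == []

    def test_study_sized_cohort_group_labels(self, small_game):
        game, base = small_game
        spec = CohortSpec(n_controls=9, n_patients=13, game=game, master_seed=1,
                          base_params=base)
        sessions = simulate_cohort(spec)
        assert len(sessions) == 22
        assert sum(s.group == "control" for s in sessions) == 9
        assert sum(s.group == "patient" for s in sessions) == 13

    def test_cohort_determinism(self, small_game):
        game, base = small_game
        spec = CohortSpec(n_controls=2, n_patients=3, game=game, master_seed=4,
                          base_params=base)
        t1, f1 = sessions_to_tables(simulate_cohort(spec))
        t2, f2 = sessions_to_tables(simulate_cohort(spec))
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(f1, f2)


class TestFixtureCohort:
    def test_fixture_is_small_and_valid(self, fixture_cohort):
        sessions, expected = fixture_cohort
        assert len(sessions) <= 7
        assert all(len(s.trials) <= 10 for s in sessions)
        for s in sessions:
            s.validate()
        assert {"player_id", "metric", "level", "value"} <= set(expected.columns)

    def test_fixture_runs_pipeline_without_warnings(self, fixture_cohort, recwarn):
        import warnings

        from vrsearch.atypicality import build_summary_matrix

        sessions, _ = fixture_cohort
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            m = build_summary_matrix([compute_metric_vector(s) for s in sessions])
        assert m.cells.shape == (7, 14)
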