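"""Synthetic participants: pen simulation, pool, judgments, session assembly."""

import dataclasses

import numpy as np
import pytest

from agencysim import (
    Condition,
    ParticipantProfile,
    assemble_session,
    build_pool,
    default_profiles,
    simulate_judgment,
    simulate_pen,
)
from agencysim.behavior import draw_condition_order
from agencysim.errors import ConfigurationError, PoolError


class TestSimulatePen:
    def test_noiseless_pen_tracks_target_exactly(self, path):
        quiet = ParticipantProfile(motor_noise_sigma=0.0, drift_mu=0.0)
        traj = simulate_pen(quiet, path, True, seed=0)
        assert np.allclose(traj.y_px, path.y_at_time(traj.t_s), atol=1e-12)

    def test_same_seed_reproduces_trajectory(self, profiles, path):
        a = simulate_pen(profiles["pb_like"], path, False, seed=7)
        b = simulate_pen(profiles["pb_like"], path, False, seed=7)
        assert a.equals(b)

    def test_sampling_grid(self, profiles, path):
        traj = simulate_pen(profiles["pb_like"], path, True, seed=1)
        assert traj.n_samples == 361  # 6 s at 60 Hz, both endpoints
        assert traj.t_s[0] == 0.0 and traj.t_s[-1] == pytest.approx(6.0)
        assert traj.dt_s == pytest.approx(1 / 60)

    def test_vision_reduces_tracing_error(self, path):
        """Visual correction keeps mean |error| below the proprioceptive regime."""
        prof = ParticipantProfile(visual_gain=0.9, proprio_gain=0.05,
                                  motor_noise_sigma=40.0)
        rng = np.random.default_rng(2024)
        errs = {True: [], False: []}
        for _ in range(500):
            for flag in (True, False):
                traj = simulate_pen(prof, path, flag, rng=rng)
                errs[flag].append(np.abs(traj.y_px - path.y_at_time(traj.t_s)).mean())
        assert np.mean(errs[True]) < np.mean(errs[False])

    def test_nonfinite_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            ParticipantProfile(motor_noise_sigma=float("nan"))
        with pytest.raises(ConfigurationError):
            ParticipantProfile(visual_gain=0.3, proprio_gain=0.5)


class TestPool:
    def test_default_pool_counts(self, profiles, path):
        pool = build_pool(profiles["pb_like"], path, seed=0)
        assert len(pool.practice_trials) == 25
        assert len(pool.eligible_indices) == 20
        assert set(pool.eligible_indices) & set(range(5)) == set()

    def test_single_trial_pool(self, profiles, path):
        pool = build_pool(profiles["pb_like"], path, n_practice=1, n_excluded=0, seed=0)
        assert pool.eligible_indices == (0,)

    def test_exclusion_must_leave_trials(self, profiles, path):
        with pytest.raises(PoolError):
            build_pool(profiles["pb_like"], path, n_practice=5, n_excluded=5, seed=0)


class TestJudgment:
    quiet = dict(judgment_noise_sigma=0.0)

    @pytest.mark.parametrize(
        "w,beta,d_over_tau,expected",
        [
            (1.0, 0.5, 0.0, 9),   # perfect sensorimotor match
            (1.0, 0.5, 1.0, 1),   # saturated mismatch
            (1.0, 0.5, 2.0, 1),   # saturation clamps beyond tau
            (0.0, 1.0, 0.7, 9),   # purely prior-driven self-attribution
            (0.5, 0.5, 0.5, 5),   # mid-scale: latent exactly 5
        ],
    )
    def test_noiseless_rule(self, w, beta, d_over_tau, expected):
        prof = ParticipantProfile(cue_weight=w, prior_self_belief=beta,
                                  tolerance_px=400.0, **self.quiet)
        assert simulate_judgment(prof, d_over_tau * 400.0) == expected

    def test_prior_driven_judgments_constant_in_error(self):
        prof = ParticipantProfile(cue_weight=0.0, prior_self_belief=1.0, **self.quiet)
        assert len({simulate_judgment(prof, d) for d in (0, 50, 200, 1000)}) == 1

    def test_negative_error_rejected(self, profiles):
        with pytest.raises(ValueError):
            simulate_judgment(profiles["pb_like"], -1.0)

    def test_noise_respects_scale_bounds(self, profiles):
        rng = np.random.default_rng(0)
        noisy = dataclasses.replace(profiles["pa_like"], judgment_noise_sigma=5.0)
        js = [simulate_judgment(noisy, 100.0, rng=rng) for _ in range(200)]
        assert all(1 <= j <= 9 for j in js)


class TestSession:
    def test_default_composition(self, pb_session):
        assert len(pb_session.trials) == 32
        assert pb_session.condition_counts() == {"SELF": 16, "FAKE": 16}
        assert len(pb_session.sample_trials) == 8
        sample_counts = [t.condition for t in pb_session.sample_trials]
        assert sample_counts.count(Condition.SELF) == 4

    def test_self_cursor_is_pen(self, pb_session):
        for tr in pb_session.trials:
            if tr.condition is Condition.SELF:
                assert tr.cursor.equals(tr.pen)
                assert tr.replay_source_index is None

    def test_fake_sources_distinct_and_eligible(self, pb_session):
        sources = [t.replay_source_index for t in pb_session.trials
                   if t.condition is Condition.FAKE]
        assert len(sources) == len(set(sources)) == 16
        assert set(sources) <= set(pb_session.pool.eligible_indices)

    def test_fake_cursor_is_the_named_practice_trial(self, pb_session):
        for tr in pb_session.trials:
            if tr.condition is Condition.FAKE:
                assert tr.cursor.equals(
                    pb_session.pool.practice_trials[tr.replay_source_index]
                )

    def test_all_judgments_on_scale(self, pb_session):
        assert all(t.judgment in range(1, 10) for t in pb_session.trials)

    def test_pool_cannot_be_overdrawn(self, profiles, path):
        with pytest.raises(PoolError):
            assemble_session(profiles["pb_like"], path, n_fake=21, seed=0)

    def test_first_trial_condition_is_balanced_across_seeds(self):
        rng_first = [
            draw_condition_order(16, 16, np.random.default_rng(s))[0]
            for s in range(500)
        ]
        frac_self = np.mean([c is Condition.SELF for c in rng_first])
        assert 0.35 <= frac_self <= 0.65
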