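"""Movement-error, prediction-error and incorrect-response indices."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agencysim import (
    Condition,
    TargetPath,
    Trajectory,
    TrialRecord,
    build_visibility,
    incorrect_response,
    movement_error,
    prediction_error,
)
from agencysim.errors import InsufficientSamplesError

finite = st.floats(min_value=-500, max_value=500, allow_nan=False)


def paced_pen(path, y_offset=0.0, refresh_hz=60.0):
    """Pen trajectory riding the paced target with a vertical offset (scalar or array)."""
    n = round(path.duration_s * refresh_hz)
    t = np.arange(n + 1) / refresh_hz
    x = path.x_start_px + (path.x_end_px - path.x_start_px) * t / path.duration_s
    return Trajectory(t, x, path.y_at_time(t) + y_offset)


def make_trial(path, pen, cursor=None, condition=Condition.FAKE):
    vis = build_visibility(path)
    cursor = pen if cursor is None else cursor
    src = 0 if condition is Condition.FAKE else None
    return TrialRecord(0, condition, pen, cursor, vis, replay_source_index=src)


class TestMovementError:
    def test_perfect_tracing_scores_zero(self, path):
        me = movement_error(make_trial(path, paced_pen(path)), path)
        assert me.per_cycle_mean_px == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
        assert me.baseline_subtracted_px == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)
        assert me.baseline_subtracted_px[0] == 0.0  # cycle 1 exact by construction

    def test_constant_offset_removed_by_baseline(self, path):
        me = movement_error(make_trial(path, paced_pen(path, 10.0)), path)
        assert me.per_cycle_mean_px == pytest.approx((10.0, 10.0, 10.0))
        assert me.baseline_subtracted_px == pytest.approx((0.0, 0.0, 0.0))

    def test_per_cycle_offsets_survive_baseline(self, path):
        """Offsets 0/30/50 px in cycles 1-3 give baseline-subtracted (0, 30, 50)."""
        pen = paced_pen(path)
        offset = np.where(pen.t_s < 2.0, 0.0, np.where(pen.t_s < 4.0, 30.0, 50.0))
        trial = make_trial(path, Trajectory(pen.t_s, pen.x_px, pen.y_px + offset))
        me = movement_error(trial, path)
        assert me.baseline_subtracted_px == pytest.approx((0.0, 30.0, 50.0))
        assert me.baseline_subtracted_px[0] == 0.0  # exact, by construction

    def test_unsigned_distance(self, path):
        below = movement_error(make_trial(path, paced_pen(path, -25.0)), path)
        assert below.per_cycle_mean_px == pytest.approx((25.0, 25.0, 25.0))

    @given(dy=finite)
    def test_shifting_pen_and_target_together_changes_nothing(self, dy):
        path = TargetPath()
        shifted_path = dataclasses.replace(path, y_center_px=path.y_center_px + dy)
        base = movement_error(make_trial(path, paced_pen(path, 12.0)), path)
        moved = movement_error(
            make_trial(shifted_path, paced_pen(shifted_path, 12.0)), shifted_path
        )
        assert base.per_cycle_mean_px == pytest.approx(moved.per_cycle_mean_px)


class TestPredictionError:
    def test_self_trials_are_exactly_zero(self, path):
        pen = paced_pen(path, 17.0)
        trial = make_trial(path, pen, condition=Condition.SELF)
        assert prediction_error(trial).mean_pen_cursor_distance_px == 0.0

    def test_three_four_five_offset(self, path):
        pen = paced_pen(path)
        cursor = Trajectory(pen.t_s, pen.x_px + 3.0, pen.y_px + 4.0)
        assert prediction_error(make_trial(path, pen, cursor)).mean_pen_cursor_distance_px \
            == pytest.approx(5.0)

    def test_piecewise_offset_averages_over_visible_window(self, path):
        """0 px for half of the visible samples and 100 px for the other half -> 50."""
        pen = paced_pen(path)
        vis_idx = np.nonzero(build_visibility(path).visible_mask(pen.t_s))[0]
        offset = np.zeros(pen.n_samples)
        offset[vis_idx[len(vis_idx) // 2:]] = 100.0
        offset[~np.isin(np.arange(pen.n_samples), vis_idx)] = 999.0  # masked: ignored
        cursor = Trajectory(pen.t_s, pen.x_px, pen.y_px + offset)
        assert prediction_error(make_trial(path, pen, cursor)).mean_pen_cursor_distance_px \
            == pytest.approx(50.0)

    @given(dx=finite, dy=finite)
    def test_common_translation_invariance(self, dx, dy):
        path = TargetPath()
        pen = paced_pen(path, 5.0)
        cursor = Trajectory(pen.t_s, pen.x_px + 7.0, pen.y_px - 11.0)
        d0 = prediction_error(make_trial(path, pen, cursor)).mean_pen_cursor_distance_px
        pen2 = Trajectory(pen.t_s, pen.x_px + dx, pen.y_px + dy)
        cur2 = Trajectory(cursor.t_s, cursor.x_px + dx, cursor.y_px + dy)
        d1 = prediction_error(make_trial(path, pen2, cur2)).mean_pen_cursor_distance_px
        assert d1 == pytest.approx(d0, rel=1e-12, abs=1e-9)


class TestIncorrectResponse:
    @pytest.mark.parametrize(
        "judgments,condition,expected",
        [
            ([1] * 16, Condition.FAKE, 0.0),      # perfect other-attribution
            ([9] * 16, Condition.SELF, 0.0),      # perfect self-attribution
            ([9] * 16, Condition.FAKE, 8.0),      # complete misattribution
            ([8] * 12 + [7] * 4, Condition.FAKE, 6.75),  # mean 7.75 maps to 6.75
        ],
    )
    def test_scores(self, judgments, condition, expected):
        assert incorrect_response(judgments, condition).score == pytest.approx(expected)

    @given(st.lists(st.integers(min_value=1, max_value=9), min_size=1, max_size=40))
    def test_self_and_fake_deviations_are_complementary(self, judgments):
        s = incorrect_response(judgments, Condition.SELF).score
        f = incorrect_response(judgments, Condition.FAKE).score
        assert s + f == pytest.approx(8.0)
        assert 0.0 <= s <= 8.0 and 0.0 <= f <= 8.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            incorrect_response([], Condition.SELF)
        with pytest.raises(ValueError):
            incorrect_response([0, 5], Condition.FAKE)
        with pytest.raises(ValueError):
            incorrect_response([10], Condition.SELF)


def test_empty_cycle_window_rejected():
    path = TargetPath()
    short = Trajectory(
        np.arange(61) / 60.0,
        np.linspace(path.x_start_px, path.x_end_px / 6, 61),
        np.full(61, path.y_center_px),
    )
    with pytest.raises(InsufficientSamplesError):
        movement_error(make_trial(path, short), path)
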