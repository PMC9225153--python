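"""Trial indices: movement error, prediction error, incorrect-response score.

Three behavioral indices:

* movement error — per-cycle mean vertical distance between the pen and the
  target line, with the cycle-1 mean subtracted as a baseline (cycle 1 is
  always fully masked, so it reflects unguided tracing in both conditions);
* prediction error — per-trial mean Euclidean pen-cursor distance over the
  cursor-visible samples (identically zero on SELF trials, where the cursor
  replays the pen);
* incorrect-response score — mean deviation of the 9-point judgments from the
  condition's correct pole (9 for SELF, 1 for FAKE), a 0-8 misattribution
  index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .behavior import Condition, SessionRecord, Trajectory, TrialRecord
from .errors import InsufficientSamplesError
from .geometry import TargetPath, VisibilitySchedule

__all__ = [
    "MovementErrorProfile",
    "PredictionErrorIndex",
    "IncorrectResponseScore",
    "movement_error",
    "prediction_error",
    "incorrect_response",
    "mean_pen_cursor_distance",
    "score_session",
]


@dataclass(frozen=True)
class MovementErrorProfile:
    """Per-cycle mean vertical pen-target distances and their baseline-subtracted values."""

    per_cycle_mean_px: tuple[float, ...]
    baseline_subtracted_px: tuple[float, ...]


@dataclass(frozen=True)
class PredictionErrorIndex:
    """Mean pen-cursor Euclidean distance of one trial (px)."""

    trial_index: int
    mean_pen_cursor_distance_px: float


@dataclass(frozen=True)
class IncorrectResponseScore:
    """Mean deviation from the correct judgment pole for one condition (0-8)."""

    condition: Condition
    score: float


def mean_pen_cursor_distance(
    pen: Trajectory, cursor: Trajectory, visibility: VisibilitySchedule
) -> float:
    """Mean Euclidean pen-cursor distance over cursor-visible samples."""
    mask = visibility.visible_mask(pen.t_s)
    if not mask.any():
        raise InsufficientSamplesError("no cursor-visible samples in the trial")
    d = np.hypot(pen.x_px - cursor.x_px, pen.y_px - cursor.y_px)
    return float(d[mask].mean())


def movement_error(trial: TrialRecord, path: TargetPath) -> MovementErrorProfile:
    """Per-cycle mean |pen_y - target_y| at the pen's horizontal position.

    The distance is taken to the target *line* (the curve y(x)), not to the
    paced target point, and is unsigned.  The cycle-1 mean is subtracted from
    every cycle, so the first baseline-subtracted value is exactly zero.
    """
    pen = trial.pen
    target_y = path.y_at_x(pen.x_px)
    abs_err = np.abs(pen.y_px - target_y)
    p = path.cycle_period_s
    means = []
    for k in range(path.n_cycles):
        in_cycle = (pen.t_s >= k * p) & (pen.t_s < (k + 1) * p)
        if not in_cycle.any():
            raise InsufficientSamplesError(f"no pen samples in cycle {k + 1}")
        means.append(float(abs_err[in_cycle].mean()))
    baseline = means[0]
    return MovementErrorProfile(tuple(means), tuple(m - baseline for m in means))


def prediction_error(trial: TrialRecord) -> PredictionErrorIndex:
    """Per-trial mean pen-cursor distance; exactly zero for SELF trials."""
    if trial.condition is Condition.SELF:
        return PredictionErrorIndex(trial.trial_index, 0.0)
    d = mean_pen_cursor_distance(trial.pen, trial.cursor, trial.visibility)
    return PredictionErrorIndex(trial.trial_index, d)


def incorrect_response(
    judgments: Sequence[int], condition: Condition | str
) -> IncorrectResponseScore:
    """Misattribution score: 9 - mean(judgments) for SELF, mean(judgments) - 1 for FAKE."""
    condition = Condition(condition)
    judgments = list(judgments)
    if not judgments:
        raise ValueError("judgments must be non-empty")
    if any(int(j) != j or not 1 <= j <= 9 for j in judgments):
        raise ValueError("judgments must be integers in 1..9")
    mean = float(np.mean(judgments))
    score = 9.0 - mean if condition is Condition.SELF else mean - 1.0
    return IncorrectResponseScore(condition, score)


def score_session(
    session: SessionRecord, path: TargetPath | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score every main trial of a session.

    Returns
    -------
    per_trial : DataFrame
        One row per trial: ``trial, condition, mean_pen_cursor_px, judgment,
        replay_source_index``.
    movement : DataFrame
        Long layout, one row per (trial, cycle): ``trial, condition, cycle,
        mean_err_px, baseline_subtracted_px`` — plus the per-condition pooled
        layout is a groupby away.
    incorrect : DataFrame
        One row per condition: ``condition, incorrect_response``.
    """
    if path is None:
        path = session.path
    trial_rows, movement_rows = [], []
    judgments: dict[Condition, list[int]] = {Condition.SELF: [], Condition.FAKE: []}
    for tr in session.trials:
        pe = prediction_error(tr)
        trial_rows.append(
            {
                "trial": tr.trial_index,
                "condition": tr.condition.value,
                "mean_pen_cursor_px": pe.mean_pen_cursor_distance_px,
                "judgment": tr.judgment,
                "replay_source_index": tr.replay_source_index,
            }
        )
        me = movement_error(tr, path)
        for cyc, (m, b) in enumerate(zip(me.per_cycle_mean_px, me.baseline_subtracted_px), 1):
            movement_rows.append(
                {
                    "trial": tr.trial_index,
                    "condition": tr.condition.value,
                    "cycle": cyc,
                    "mean_err_px": m,
                    "baseline_subtracted_px": b,
                }
            )
        if tr.judgment is not None:
            judgments[tr.condition].append(tr.judgment)
    incorrect_rows = [
        {"condition": cond.value, "incorrect_response": incorrect_response(js, cond).score}
        for cond, js in judgments.items()
        if js
    ]
    return (
        pd.DataFrame(trial_rows),
        pd.DataFrame(movement_rows),
        pd.DataFrame(incorrect_rows),
    )
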