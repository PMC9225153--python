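"""Reading and writing sessions and score tables as plain-text artifacts.

A session serializes to three files in a directory:

* ``trials.csv`` — per-sample rows for every trial (main and sample blocks):
  ``phase, trial, condition, t_s, pen_x, pen_y, cur_x, cur_y, visible``;
* ``pool.csv`` — per-sample rows of the practice pool trajectories;
* ``session.json`` — participant profile, seed, geometry/timing echo,
  per-trial metadata (condition, replay source, judgment) and pool metadata.

Writing is deterministic: the same session object produces byte-identical
files, so identical (config, seed) runs serialize identically.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import (
    Condition,
    ParticipantProfile,
    PrerecordedPool,
    SessionRecord,
    Trajectory,
    TrialRecord,
)
from .geometry import TargetPath, VisibilitySchedule

__all__ = ["session_to_frames", "write_session", "read_session"]

TRIALS_FILE = "trials.csv"
POOL_FILE = "pool.csv"
META_FILE = "session.json"


def _trajectory_rows(traj: Trajectory, visibility: VisibilitySchedule) -> dict:
    return {
        "t_s": traj.t_s,
        "visible": visibility.visible_mask(traj.t_s).astype(int),
    }


def session_to_frames(session: SessionRecord) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a session into (trials table, pool table)."""
    blocks = []
    for phase, trials in (("sample", session.sample_trials), ("main", session.trials)):
        for tr in trials:
            vis = tr.visibility.visible_mask(tr.pen.t_s).astype(int)
            blocks.append(
                pd.DataFrame(
                    {
                        "phase": phase,
                        "trial": tr.trial_index,
                        "condition": tr.condition.value,
                        "t_s": tr.pen.t_s,
                        "pen_x": tr.pen.x_px,
                        "pen_y": tr.pen.y_px,
                        "cur_x": tr.cursor.x_px,
                        "cur_y": tr.cursor.y_px,
                        "visible": vis,
                    }
                )
            )
    trials_df = pd.concat(blocks, ignore_index=True)
    pool_blocks = [
        pd.DataFrame(
            {"practice_trial": i, "t_s": tr.t_s, "x_px": tr.x_px, "y_px": tr.y_px}
        )
        for i, tr in enumerate(session.pool.practice_trials)
    ]
    pool_df = pd.concat(pool_blocks, ignore_index=True)
    return trials_df, pool_df


def _meta_dict(session: SessionRecord) -> dict:
    def trial_meta(tr: TrialRecord) -> dict:
        return {
            "trial": tr.trial_index,
            "condition": tr.condition.value,
            "replay_source_index": tr.replay_source_index,
            "judgment": tr.judgment,
        }

    return {
        "format": "agencysim-session-v1",
        "rng_seed": session.rng_seed,
        "refresh_hz": session.refresh_hz,
        "participant": dataclasses.asdict(session.participant),
        "path": dataclasses.asdict(session.path),
        "visibility": {
            "masked_intervals": [list(iv) for iv in session.visibility.masked_intervals],
            "total_duration_s": session.visibility.total_duration_s,
        },
        "pool": {
            "n_practice": len(session.pool.practice_trials),
            "eligible_indices": list(session.pool.eligible_indices),
        },
        "trials": [trial_meta(t) for t in session.trials],
        "sample_trials": [trial_meta(t) for t in session.sample_trials],
    }


def write_session(session: SessionRecord, out_dir: str | Path) -> Path:
    """Write trials.csv, pool.csv and session.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials_df, pool_df = session_to_frames(session)
    trials_df.to_csv(out / TRIALS_FILE, index=False)
    pool_df.to_csv(out / POOL_FILE, index=False)
    (out / META_FILE).write_text(
        json.dumps(_meta_dict(session), indent=2, sort_keys=True) + "\n"
    )
    return out


def read_session(in_dir: str | Path) -> SessionRecord:
    """Reconstruct a :class:`SessionRecord` written by :func:`write_session`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / META_FILE).read_text())
    trials_df = pd.read_csv(in_dir / TRIALS_FILE)
    pool_df = pd.read_csv(in_dir / POOL_FILE)

    profile = ParticipantProfile(**meta["participant"])
    path = TargetPath(**meta["path"])
    visibility = VisibilitySchedule(
        tuple(tuple(iv) for iv in meta["visibility"]["masked_intervals"]),
        meta["visibility"]["total_duration_s"],
    )
    pool_trials = tuple(
        Trajectory(g["t_s"].to_numpy(), g["x_px"].to_numpy(), g["y_px"].to_numpy())
        for _, g in pool_df.groupby("practice_trial", sort=True)
    )
    pool = PrerecordedPool(pool_trials, tuple(meta["pool"]["eligible_indices"]))

    def build_trials(phase: str, metas: list[dict]) -> tuple[TrialRecord, ...]:
        sub = trials_df[trials_df["phase"] == phase]
        out = []
        for m in metas:
            g = sub[sub["trial"] == m["trial"]]
            pen = Trajectory(g["t_s"].to_numpy(), g["pen_x"].to_numpy(), g["pen_y"].to_numpy())
            cond = Condition(m["condition"])
            if cond is Condition.SELF:
                cursor = pen
            else:
                cursor = Trajectory(
                    g["t_s"].to_numpy(), g["cur_x"].to_numpy(), g["cur_y"].to_numpy()
                )
            out.append(
                TrialRecord(
                    m["trial"], cond, pen, cursor, visibility,
                    replay_source_index=m["replay_source_index"],
                    judgment=m["judgment"],
                )
            )
        return tuple(out)

    return SessionRecord(
        participant=profile,
        pool=pool,
        trials=build_trials("main", meta["trials"]),
        rng_seed=meta["rng_seed"],
        sample_trials=build_trials("sample", meta["sample_trials"]),
        path=path,
        visibility=visibility,
        refresh_hz=meta["refresh_hz"],
    )
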