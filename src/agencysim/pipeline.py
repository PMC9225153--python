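"""End-to-end orchestration: simulate -> score -> correlate -> report.

``run_session`` simulates one participant-session, scores it and correlates
prediction errors with judgments in the FAKE condition.  ``run_comparison``
repeats that over many seeds for several participant profiles and summarizes
the between-profile contrast — the generative analogue of comparing a
misattributing patient against a prediction-error-driven one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as session_io
from .association import MAGNITUDE_BOUNDS, CorrelationResult, correlate
from .behavior import (
    Condition,
    ParticipantProfile,
    SessionRecord,
    assemble_session,
    default_profiles,
)
from .errors import ConfigurationError, DegenerateVarianceError
from .geometry import CanvasSpec, TargetPath
from .scoring import score_session

__all__ = ["RunConfig", "ScoreReport", "ComparisonReport", "run_session", "run_comparison"]

logger = logging.getLogger("agencysim")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: geometry, counts, profiles."""

    canvas: CanvasSpec = field(default_factory=CanvasSpec)
    path: TargetPath = field(default_factory=TargetPath)
    mask_lead_s: float = 0.5
    mask_tail_s: float = 0.5
    n_self: int = 16
    n_fake: int = 16
    n_sample_self: int = 4
    n_sample_fake: int = 4
    n_practice: int = 25
    n_practice_excluded: int = 5
    magnitude_bounds: tuple[float, float, float] = MAGNITUDE_BOUNDS
    profiles: dict[str, ParticipantProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        counts = (self.n_self, self.n_fake, self.n_sample_self, self.n_sample_fake,
                  self.n_practice)
        if any(c <= 0 for c in counts):
            raise ConfigurationError("all trial counts must be positive")
        if self.n_fake > self.n_practice - self.n_practice_excluded:
            raise ConfigurationError("n_fake exceeds the eligible practice pool")
        if not self.profiles:
            raise ConfigurationError("at least one participant profile is required")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["magnitude_bounds"] = list(self.magnitude_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["canvas"] = CanvasSpec(**d.get("canvas", {}))
        d["path"] = TargetPath(**d.get("path", {}))
        d["magnitude_bounds"] = tuple(d.get("magnitude_bounds", MAGNITUDE_BOUNDS))
        d["profiles"] = {
            name: ParticipantProfile(**p) for name, p in d.get("profiles", {}).items()
        } or default_profiles()
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass(frozen=True, eq=False)
class ScoreReport:
    """All indices of one session plus the FAKE-condition correlation."""

    per_trial: pd.DataFrame
    movement: pd.DataFrame
    incorrect: pd.DataFrame
    correlation: CorrelationResult | None

    def movement_by_condition(self) -> pd.DataFrame:
        """Per-condition per-cycle means with the cycle-1 baseline re-subtracted."""
        g = (
            self.movement.groupby(["condition", "cycle"])["mean_err_px"]
            .mean()
            .reset_index()
        )
        base = g[g["cycle"] == 1].set_index("condition")["mean_err_px"]
        g["baseline_subtracted_px"] = g["mean_err_px"] - g["condition"].map(base)
        return g

    def incorrect_scores(self) -> dict[str, float]:
        return dict(
            zip(self.incorrect["condition"], self.incorrect["incorrect_response"])
        )


def _score_and_correlate(session: SessionRecord, config: RunConfig) -> ScoreReport:
    per_trial, movement, incorrect = score_session(session, config.path)
    fake = per_trial[per_trial["condition"] == Condition.FAKE.value]
    correlation: CorrelationResult | None
    try:
        correlation = correlate(
            fake["mean_pen_cursor_px"].to_numpy(),
            fake["judgment"].to_numpy(dtype=float),
            bounds=config.magnitude_bounds,
        )
    except DegenerateVarianceError:
        # a participant whose judgments never vary (pure-prior limit)
        correlation = None
    return ScoreReport(per_trial, movement, incorrect, correlation)


def run_session(
    config: RunConfig,
    profile_name: str,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[SessionRecord, ScoreReport, CorrelationResult | None]:
    """Simulate, score and correlate one session; optionally write artifacts."""
    if profile_name not in config.profiles:
        raise ConfigurationError(f"unknown profile {profile_name!r}")
    profile = config.profiles[profile_name]
    logger.info("session: profile=%s seed=%d", profile_name, seed)
    session = assemble_session(
        profile,
        config.path,
        n_self=config.n_self,
        n_fake=config.n_fake,
        n_sample_self=config.n_sample_self,
        n_sample_fake=config.n_sample_fake,
        n_practice=config.n_practice,
        n_practice_excluded=config.n_practice_excluded,
        mask_lead_s=config.mask_lead_s,
        mask_tail_s=config.mask_tail_s,
        refresh_hz=config.canvas.refresh_hz,
        seed=seed,
    )
    report = _score_and_correlate(session, config)
    if out_dir is not None:
        out = Path(out_dir)
        session_io.write_session(session, out)
        write_scores(report, out)
        manifest = {
            "config": config.to_dict(),
            "config_sha256": config.sha256,
            "profile": profile_name,
            "seed": seed,
            "package": "agencysim",
            "version": _version(),
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return session, report, report.correlation


def write_scores(report: ScoreReport, out_dir: str | Path) -> Path:
    """Write the score tables and the correlation line as delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_trial.to_csv(out / "scores_per_trial.csv", index=False)
    report.movement.to_csv(out / "movement_per_cycle.csv", index=False)
    report.movement_by_condition().to_csv(out / "movement_by_condition.csv", index=False)
    report.incorrect.to_csv(out / "incorrect_response.csv", index=False)
    corr = report.correlation
    pd.DataFrame(
        [
            {
                "r": corr.r if corr else np.nan,
                "n": corr.n if corr else 0,
                "p_two_tailed": corr.p_two_tailed if corr else np.nan,
                "magnitude": corr.magnitude_label if corr else "undefined",
            }
        ]
    ).to_csv(out / "correlation.csv", index=False)
    return out


@dataclass(frozen=True, eq=False)
class ComparisonReport:
    """Across-seed comparison of participant profiles."""

    rows: pd.DataFrame          # one row per (profile, seed)
    scatter: pd.DataFrame       # per-trial (profile, seed, D, judgment), FAKE only
    config: RunConfig

    def summary(self) -> pd.DataFrame:
        g = self.rows.groupby("profile")
        out = g.agg(
            n_seeds=("seed", "size"),
            incorrect_self=("incorrect_self", "mean"),
            incorrect_fake=("incorrect_fake", "mean"),
            mean_abs_r=("abs_r", "mean"),
            self_lt_fake_frac=("self_lt_fake", "mean"),
        )
        return out.reset_index()

    def summary_text(self) -> str:
        s = self.summary()
        lines = [
            "Self-other attribution summary (means over seeds)",
            "profile        n    incorrect_SELF  incorrect_FAKE  mean|r|  SELF<FAKE",
        ]
        for _, row in s.iterrows():
            lines.append(
                f"{row['profile']:<13} {row['n_seeds']:>4} "
                f"{row['incorrect_self']:>14.2f}  {row['incorrect_fake']:>14.2f}  "
                f"{row['mean_abs_r']:>7.2f}  {row['self_lt_fake_frac']:>8.1%}"
            )
        return "\n".join(lines)


def run_comparison(
    config: RunConfig,
    seeds: Sequence[int],
    profile_names: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> ComparisonReport:
    """Run every (profile, seed) session and collect the contrast table.

    Each row carries the session's incorrect-response scores, the FAKE-trial
    correlation, and the per-condition movement-error summaries (mean
    baseline-subtracted error over cycles >= 2).
    """
    seeds = list(seeds)
    if not seeds:
        raise ConfigurationError("seed list must be non-empty")
    if profile_names is None:
        profile_names = list(config.profiles)
    if not profile_names:
        raise ConfigurationError("need at least one profile")

    rows, scatter = [], []
    for name in profile_names:
        for seed in seeds:
            session, report, corr = run_session(config, name, seed)
            inc = report.incorrect_scores()
            mbc = report.movement_by_condition()
            later = mbc[mbc["cycle"] >= 2]
            move = later.groupby("condition")["baseline_subtracted_px"].mean()
            move_self = float(move.get(Condition.SELF.value, np.nan))
            move_fake = float(move.get(Condition.FAKE.value, np.nan))
            rows.append(
                {
                    "profile": name,
                    "seed": seed,
                    "incorrect_self": inc.get(Condition.SELF.value, np.nan),
                    "incorrect_fake": inc.get(Condition.FAKE.value, np.nan),
                    "r": corr.r if corr else np.nan,
                    "abs_r": abs(corr.r) if corr else np.nan,
                    "p_two_tailed": corr.p_two_tailed if corr else np.nan,
                    "magnitude": corr.magnitude_label if corr else "undefined",
                    "movement_self_px": move_self,
                    "movement_fake_px": move_fake,
                    "self_lt_fake": move_self < move_fake,
                }
            )
            fake = report.per_trial[report.per_trial["condition"] == Condition.FAKE.value]
            sc = fake[["trial", "mean_pen_cursor_px", "judgment"]].copy()
            sc.insert(0, "seed", seed)
            sc.insert(0, "profile", name)
            scatter.append(sc)

    report = ComparisonReport(
        pd.DataFrame(rows), pd.concat(scatter, ignore_index=True), config
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.rows.to_csv(out / "comparison_rows.csv", index=False)
        report.scatter.to_csv(out / "comparison_scatter.csv", index=False)
        report.summary().to_csv(out / "comparison_summary.csv", index=False)
        (out / "comparison_summary.txt").write_text(report.summary_text() + "\n")
    return report


def _version() -> str:
    from . import __version__

    return __version__
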