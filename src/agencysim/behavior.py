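"""Synthetic participants, pen/cursor trajectories and full sessions.

A synthetic participant traces the paced sine target.  Horizontal progression
is beep-locked (identical to the target's), while the vertical tracing error
follows a discrete mean-reverting (Ornstein-Uhlenbeck-style) random walk whose
reversion gain depends on whether visual feedback is currently useful:

    e(t+dt) = e(t) * (1 - g * dt * kappa) + drift_mu * dt
              + motor_noise_sigma * sqrt(dt) * eta,   eta ~ N(0, 1)

with ``g = visual_gain`` when vision is useful and ``g = proprio_gain``
otherwise (kappa = 1 / s, so gains read as per-second correction rates).

Conditions:

* SELF — the cursor replays the live pen movement sample-for-sample; pen
  control is visual inside the cursor-visible window, proprioceptive outside.
* FAKE — the cursor replays a prerecorded practice trajectory; the cursor is
  never informative, so pen control is proprioceptive throughout.

Each trial ends with a 9-point self-other judgment (9 = completely my
movement, 1 = completely another's), generated from the trial's mean
pen-cursor distance D by a weighted cue-integration rule:

    latent = 9 - 8 * [ w * min(D / tau, 1) + (1 - w) * (1 - beta) ] + noise

rounded half-up and clamped to 1..9.  ``w`` weights the sensorimotor cue
(prediction error), ``beta`` is the prior tendency to judge "self", and
``tau`` is the prediction-error tolerance: the distance at which the
sensorimotor cue saturates toward "other".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigurationError, PoolError
from .geometry import TargetPath, VisibilitySchedule, build_visibility, target_position

__all__ = [
    "KAPPA_PER_S",
    "Condition",
    "ParticipantProfile",
    "Trajectory",
    "TrialRecord",
    "PrerecordedPool",
    "SessionRecord",
    "default_profiles",
    "simulate_pen",
    "build_pool",
    "simulate_judgment",
    "assemble_session",
    "draw_condition_order",
]

#: Rate normalization for the error dynamics, fixed so gains are per-second.
KAPPA_PER_S = 1.0


class Condition(str, enum.Enum):
    SELF = "SELF"
    FAKE = "FAKE"


@dataclass(frozen=True)
class ParticipantProfile:
    """Motor, proprioceptive and judgment parameters of a synthetic participant.

    Parameters
    ----------
    visual_gain, proprio_gain
        Per-second error-correction rates with/without useful visual feedback,
        each in [0, 1] with ``proprio_gain <= visual_gain``.
    motor_noise_sigma
        Diffusion scale of the vertical tracing error, px * s^-1/2.
    drift_mu
        Systematic vertical drift, px/s.
    cue_weight
        Weight ``w`` in [0, 1] of the sensorimotor cue (prediction error) in
        the self-other judgment.  Low values model participants whose
        judgments decouple from prediction error.
    prior_self_belief
        Prior tendency ``beta`` in [0, 1] to judge "self" when the
        sensorimotor cue is discounted.
    tolerance_px
        Prediction-error tolerance ``tau`` (px): distance at which the
        sensorimotor cue saturates toward "other".
    judgment_noise_sigma
        Standard deviation of the latent judgment noise (scale points).
    label
        Free text; clinical metadata may be carried here verbatim and is
        never computed on.
    """

    visual_gain: float = 0.9
    proprio_gain: float = 0.05
    motor_noise_sigma: float = 40.0
    drift_mu: float = 0.0
    cue_weight: float = 0.9
    prior_self_belief: float = 0.6
    tolerance_px: float = 400.0
    judgment_noise_sigma: float = 0.5
    label: str = ""

    def __post_init__(self) -> None:
        numeric = (
            self.visual_gain,
            self.proprio_gain,
            self.motor_noise_sigma,
            self.drift_mu,
            self.cue_weight,
            self.prior_self_belief,
            self.tolerance_px,
            self.judgment_noise_sigma,
        )
        if not all(math.isfinite(v) for v in numeric):
            raise ConfigurationError("ParticipantProfile parameters must be finite")
        if not 0.0 <= self.proprio_gain <= self.visual_gain <= 1.0:
            raise ConfigurationError("need 0 <= proprio_gain <= visual_gain <= 1")
        if not 0.0 <= self.cue_weight <= 1.0:
            raise ConfigurationError("cue_weight must be in [0, 1]")
        if not 0.0 <= self.prior_self_belief <= 1.0:
            raise ConfigurationError("prior_self_belief must be in [0, 1]")
        if self.tolerance_px <= 0:
            raise ConfigurationError("tolerance_px must be > 0")
        if self.motor_noise_sigma < 0 or self.judgment_noise_sigma < 0:
            raise ConfigurationError("noise scales must be >= 0")


def default_profiles() -> dict[str, ParticipantProfile]:
    """Named reference profiles.

    ``pa_like`` down-weights the sensorimotor cue and holds a strong prior to
    self-attribute (the misattributing, low-correlation pattern); ``pb_like``
    and ``healthy_like`` weight prediction error heavily.  These are
    qualitative archetypes, not fits to any individual.
    """
    return {
        "pa_like": ParticipantProfile(cue_weight=0.15, prior_self_belief=0.9, label="PA-like"),
        "pb_like": ParticipantProfile(cue_weight=0.9, prior_self_belief=0.6, label="PB-like"),
        "healthy_like": ParticipantProfile(cue_weight=0.9, prior_self_belief=0.6, label="healthy-like"),
    }


@dataclass(frozen=True, eq=False)
class Trajectory:
    """Time-stamped positions sampled at the canvas refresh rate."""

    t_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray

    def __post_init__(self) -> None:
        t, x, y = (np.asarray(a, dtype=float) for a in (self.t_s, self.x_px, self.y_px))
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "x_px", x)
        object.__setattr__(self, "y_px", y)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 2:
            raise ConfigurationError("trajectory needs matching 1-d t/x/y with >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise ConfigurationError("trajectory times must increase at a constant interval")

    @property
    def n_samples(self) -> int:
        return int(self.t_s.size)

    @property
    def dt_s(self) -> float:
        return float(self.t_s[1] - self.t_s[0])

    def equals(self, other: "Trajectory") -> bool:
        return (
            np.array_equal(self.t_s, other.t_s)
            and np.array_equal(self.x_px, other.x_px)
            and np.array_equal(self.y_px, other.y_px)
        )


@dataclass(frozen=True, eq=False)
class TrialRecord:
    """One trial: condition, both trajectories, masking and the judgment."""

    trial_index: int
    condition: Condition
    pen: Trajectory
    cursor: Trajectory
    visibility: VisibilitySchedule
    replay_source_index: int | None = None
    judgment: int | None = None

    def __post_init__(self) -> None:
        if self.condition is Condition.SELF and not self.cursor.equals(self.pen):
            raise ConfigurationError("SELF trials require cursor identical to pen")
        if self.condition is Condition.FAKE and self.replay_source_index is None:
            raise ConfigurationError("FAKE trials require a replay_source_index")
        if self.judgment is not None and self.judgment not in range(1, 10):
            raise ConfigurationError("judgment must be an integer in 1..9")


@dataclass(frozen=True, eq=False)
class PrerecordedPool:
    """Practice trajectories eligible for FAKE replay.

    The first few practice trials are excluded as unstable; by default 25
    practice trials with the last 20 eligible.
    """

    practice_trials: tuple[Trajectory, ...]
    eligible_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.practice_trials)
        if any(i < 0 or i >= n for i in self.eligible_indices):
            raise PoolError("eligible_indices outside the practice pool")


@dataclass(frozen=True, eq=False)
class SessionRecord:
    """A full simulated session: profile, pool, ordered trials and the seed."""

    participant: ParticipantProfile
    pool: PrerecordedPool
    trials: tuple[TrialRecord, ...]
    rng_seed: int
    sample_trials: tuple[TrialRecord, ...] = ()
    path: TargetPath = field(default_factory=TargetPath)
    visibility: VisibilitySchedule | None = None
    refresh_hz: float = 60.0

    def condition_counts(self) -> dict[str, int]:
        out = {c.value: 0 for c in Condition}
        for tr in self.trials:
            out[tr.condition.value] += 1
        return out


def _resolve_vision_flags(vision_useful, t: np.ndarray) -> np.ndarray:
    if isinstance(vision_useful, (bool, np.bool_)):
        return np.full(t.shape, bool(vision_useful))
    if isinstance(vision_useful, VisibilitySchedule):
        return vision_useful.visible_mask(t)
    if callable(vision_useful):
        return np.array([bool(vision_useful(ti)) for ti in t])
    raise ConfigurationError("vision_useful must be a bool, VisibilitySchedule or callable")


def _resolve_rng(rng, seed) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def simulate_pen(
    profile: ParticipantProfile,
    path: TargetPath,
    vision_useful,
    *,
    refresh_hz: float = 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Simulate one pen trajectory over the full trial.

    ``vision_useful`` is a per-time flag (bool, :class:`VisibilitySchedule`, or
    callable ``t -> bool``) selecting the visual vs proprioceptive correction
    gain at each step.  Deterministic given ``rng``/``seed``.
    """
    rng = _resolve_rng(rng, seed)
    dt = 1.0 / refresh_hz
    n_steps = round(path.duration_s * refresh_hz)
    t = np.arange(n_steps + 1) * dt
    tx, ty = target_position(path, t)
    flags = _resolve_vision_flags(vision_useful, t[:-1])

    gains = np.where(flags, profile.visual_gain, profile.proprio_gain)
    decay = 1.0 - gains * dt * KAPPA_PER_S
    shock = profile.motor_noise_sigma * math.sqrt(dt)
    drift = profile.drift_mu * dt
    eta = rng.standard_normal(n_steps) if profile.motor_noise_sigma > 0 else np.zeros(n_steps)

    # plain-float recurrence: cheap at a few hundred steps
    e = np.empty(n_steps + 1)
    e[0] = 0.0
    acc = 0.0
    dec = decay.tolist()
    eta_l = eta.tolist()
    for i in range(n_steps):
        acc = acc * dec[i] + drift + shock * eta_l[i]
        e[i + 1] = acc
    return Trajectory(t, tx, ty + e)


def _simulate_error_matrix(
    profile: ParticipantProfile,
    gains: np.ndarray,
    dt: float,
    n_paths: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized error walks: ``(n_paths, n_steps + 1)``, shared gain schedule."""
    n_steps = gains.size
    decay = 1.0 - gains * dt * KAPPA_PER_S
    shock = profile.motor_noise_sigma * math.sqrt(dt)
    drift = profile.drift_mu * dt
    out = np.zeros((n_paths, n_steps + 1))
    e = np.zeros(n_paths)
    for i in range(n_steps):
        e = e * decay[i] + drift + shock * rng.standard_normal(n_paths)
        out[:, i + 1] = e
    return out


def build_pool(
    profile: ParticipantProfile,
    path: TargetPath,
    n_practice: int = 25,
    n_excluded: int = 5,
    *,
    visibility: VisibilitySchedule | None = None,
    refresh_hz: float = 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> PrerecordedPool:
    """Generate the practice pool whose later trials serve as FAKE replays.

    Practice trials run in the SELF regime (live cursor, same masking as main
    trials), so replays carry realistic visually-corrected kinematics.
    """
    if n_excluded >= n_practice:
        raise PoolError(f"n_excluded ({n_excluded}) must be < n_practice ({n_practice})")
    rng = _resolve_rng(rng, seed)
    if visibility is None:
        visibility = build_visibility(path)
    trials = tuple(
        simulate_pen(profile, path, visibility, refresh_hz=refresh_hz, rng=rng)
        for _ in range(n_practice)
    )
    return PrerecordedPool(trials, tuple(range(n_excluded, n_practice)))


def simulate_judgment(
    profile: ParticipantProfile,
    mean_prediction_error_px: float,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> int:
    """Draw a 9-point self-other judgment from the cue-integration rule."""
    d = float(mean_prediction_error_px)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"mean prediction error must be >= 0, got {d!r}")
    w = profile.cue_weight
    sensorimotor = min(d / profile.tolerance_px, 1.0)
    prior = 1.0 - profile.prior_self_belief
    latent = 9.0 - 8.0 * (w * sensorimotor + (1.0 - w) * prior)
    if profile.judgment_noise_sigma > 0:
        latent += _resolve_rng(rng, seed).normal(0.0, profile.judgment_noise_sigma)
    return int(min(9, max(1, math.floor(latent + 0.5))))


def draw_condition_order(
    n_self: int, n_fake: int, rng: np.random.Generator
) -> tuple[Condition, ...]:
    """Uniformly shuffled condition sequence with exact per-condition counts."""
    conds = np.array([0] * n_self + [1] * n_fake)
    return tuple(Condition.FAKE if c else Condition.SELF for c in rng.permutation(conds))


def _make_trials(
    profile: ParticipantProfile,
    path: TargetPath,
    visibility: VisibilitySchedule,
    conditions: Sequence[Condition],
    fake_sources: Sequence[int],
    pool: PrerecordedPool,
    refresh_hz: float,
    traj_rng: np.random.Generator,
    judge_rng: np.random.Generator,
) -> tuple[TrialRecord, ...]:
    from .scoring import mean_pen_cursor_distance  # local import: avoids cycle

    trials = []
    fake_iter = iter(fake_sources)
    for idx, cond in enumerate(conditions):
        if cond is Condition.SELF:
            pen = simulate_pen(profile, path, visibility, refresh_hz=refresh_hz, rng=traj_rng)
            cursor, source, d = pen, None, 0.0
        else:
            pen = simulate_pen(profile, path, False, refresh_hz=refresh_hz, rng=traj_rng)
            source = int(next(fake_iter))
            cursor = pool.practice_trials[source]
            d = mean_pen_cursor_distance(pen, cursor, visibility)
        judgment = simulate_judgment(profile, d, rng=judge_rng)
        trials.append(
            TrialRecord(idx, cond, pen, cursor, visibility,
                        replay_source_index=source, judgment=judgment)
        )
    return tuple(trials)


def assemble_session(
    profile: ParticipantProfile,
    path: TargetPath | None = None,
    *,
    n_self: int = 16,
    n_fake: int = 16,
    n_sample_self: int = 4,
    n_sample_fake: int = 4,
    n_practice: int = 25,
    n_practice_excluded: int = 5,
    mask_lead_s: float = 0.5,
    mask_tail_s: float = 0.5,
    refresh_hz: float = 60.0,
    pool: PrerecordedPool | None = None,
    seed: int = 0,
) -> SessionRecord:
    """Assemble one randomized session.

    Generates the practice pool, a block of third-practice sample trials
    (familiarization; excluded from scoring), and the main block — by default
    32 trials, 16 SELF and 16 FAKE in random order.  Main FAKE replay sources
    are drawn without replacement from the eligible pool; sample-trial sources
    are drawn independently so they never exhaust the main draw.  Judgments
    come from the cue-integration rule applied to each trial's scored mean
    pen-cursor distance (identically zero on SELF trials).  Fully
    reproducible: identical arguments and seed give an identical session.
    """
    if path is None:
        path = TargetPath()
    visibility = build_visibility(path, mask_lead_s, mask_tail_s)

    ss = np.random.SeedSequence(seed)
    pool_rng, order_rng, source_rng, traj_rng, judge_rng, sample_rng = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    if pool is None:
        pool = build_pool(
            profile, path, n_practice, n_practice_excluded,
            visibility=visibility, refresh_hz=refresh_hz, rng=pool_rng,
        )
    eligible = list(pool.eligible_indices)
    if n_fake > len(eligible):
        raise PoolError(
            f"cannot draw {n_fake} FAKE replays without replacement from "
            f"{len(eligible)} eligible practice trials"
        )

    sample_conditions = draw_condition_order(n_sample_self, n_sample_fake, sample_rng)
    sample_sources = sample_rng.choice(eligible, size=n_sample_fake, replace=False)
    sample_trials = _make_trials(
        profile, path, visibility, sample_conditions, sample_sources,
        pool, refresh_hz, sample_rng, sample_rng,
    )

    conditions = draw_condition_order(n_self, n_fake, order_rng)
    fake_sources = source_rng.choice(eligible, size=n_fake, replace=False)
    trials = _make_trials(
        profile, path, visibility, conditions, fake_sources,
        pool, refresh_hz, traj_rng, judge_rng,
    )

    return SessionRecord(
        participant=profile,
        pool=pool,
        trials=trials,
        rng_seed=seed,
        sample_trials=sample_trials,
        path=path,
        visibility=visibility,
        refresh_hz=refresh_hz,
    )
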