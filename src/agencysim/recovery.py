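"""Fitting the cue-integration judgment model to trial data.

Given per-trial prediction errors D_i and observed 9-point judgments J_i, the
model

    J_hat(D; w, beta) = clamp( round( 9 - 8*[ w*min(D/tau, 1)
                                              + (1-w)*(1-beta) ] ), 1, 9 )

is fitted by grid search over the cue weight w and the prior self-belief
beta, minimizing the sum of squared judgment errors.  The tolerance tau is
treated as known.  Exposed statsmodels-style: build a
:class:`CueIntegrationModel` from arrays or a trial table, ``fit()`` returns
a :class:`CueIntegrationResults` with parameter estimates, a near-optimal
plateau as a grid-based uncertainty summary, and ``summary()``.

``run_recovery_experiment`` measures how reliably the fit recovers a known
generating cue weight from simulated FAKE trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import (
    ParticipantProfile,
    _simulate_error_matrix,
    default_profiles,
)
from .geometry import TargetPath, build_visibility

__all__ = ["CueIntegrationModel", "CueIntegrationResults", "run_recovery_experiment"]


class CueIntegrationModel:
    """Cue-integration judgment model for observed (prediction error, judgment) pairs.

    Parameters
    ----------
    judgments : array-like of int
        Observed 9-point self-other judgments.
    prediction_errors : array-like of float
        Per-trial mean pen-cursor distances (px), same length.
    tolerance_px : float
        Known prediction-error tolerance tau (px).
    """

    def __init__(self, judgments, prediction_errors, tolerance_px: float = 400.0):
        self.judgments = np.asarray(judgments, dtype=float)
        self.prediction_errors = np.asarray(prediction_errors, dtype=float)
        if self.judgments.shape != self.prediction_errors.shape or self.judgments.ndim != 1:
            raise ValueError("judgments and prediction_errors must be 1-d and equal length")
        if np.any(self.prediction_errors < 0):
            raise ValueError("prediction errors must be >= 0")
        if tolerance_px <= 0:
            raise ValueError("tolerance_px must be > 0")
        self.tolerance_px = float(tolerance_px)
        self.nobs = int(self.judgments.size)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        judgment_col: str = "judgment",
        error_col: str = "mean_pen_cursor_px",
        tolerance_px: float = 400.0,
    ) -> "CueIntegrationModel":
        """Build from a per-trial score table (e.g. the FAKE rows of ``score_session``)."""
        return cls(df[judgment_col].to_numpy(), df[error_col].to_numpy(), tolerance_px)

    def latent(self, cue_weight, prior_self_belief) -> np.ndarray:
        """Continuous model judgment, clamped to the 1-9 scale."""
        s = np.minimum(self.prediction_errors / self.tolerance_px, 1.0)
        out = 9.0 - 8.0 * (cue_weight * s + (1.0 - cue_weight) * (1.0 - prior_self_belief))
        return np.clip(out, 1.0, 9.0)

    def predict(self, cue_weight: float, prior_self_belief: float) -> np.ndarray:
        """Deterministic integer model judgments (rounded half-up)."""
        return np.floor(self.latent(cue_weight, prior_self_belief) + 0.5).clip(1, 9)

    def fit(
        self,
        w_grid: np.ndarray | None = None,
        beta_grid: np.ndarray | None = None,
    ) -> "CueIntegrationResults":
        """Exhaustive grid search minimizing sum((J - latent)^2).

        The objective compares the observed integer judgments with the
        *continuous* clamped latent prediction: the observations already carry
        the report-scale rounding, and rounding the prediction as well turns
        the objective into a biased staircase.  Exact ties resolve to the
        median of the minimizing grid points.
        """
        w_grid = np.linspace(0.0, 1.0, 101) if w_grid is None else np.asarray(w_grid)
        beta_grid = np.linspace(0.0, 1.0, 101) if beta_grid is None else np.asarray(beta_grid)
        s = np.minimum(self.prediction_errors / self.tolerance_px, 1.0)
        w = w_grid[:, None, None]
        b = beta_grid[None, :, None]
        latent = 9.0 - 8.0 * (w * s[None, None, :] + (1.0 - w) * (1.0 - b))
        pred = np.clip(latent, 1.0, 9.0)
        sse = ((pred - self.judgments[None, None, :]) ** 2).sum(axis=2)
        ties_i, ties_j = np.nonzero(sse <= sse.min() + 1e-12)
        w_hat = float(np.median(w_grid[ties_i]))
        b_hat = float(np.median(beta_grid[ties_j]))
        return CueIntegrationResults(
            model=self,
            cue_weight=w_hat,
            prior_self_belief=b_hat,
            rss=float(sse.min()),
            w_grid=w_grid,
            beta_grid=beta_grid,
            sse_grid=sse,
        )


@dataclass(frozen=True, eq=False)
class CueIntegrationResults:
    """Grid-search fit of the cue-integration judgment model."""

    model: CueIntegrationModel
    cue_weight: float
    prior_self_belief: float
    rss: float
    w_grid: np.ndarray
    beta_grid: np.ndarray
    sse_grid: np.ndarray

    @property
    def params(self) -> dict[str, float]:
        return {"cue_weight": self.cue_weight, "prior_self_belief": self.prior_self_belief}

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.cue_weight, self.prior_self_belief)

    @property
    def resid(self) -> np.ndarray:
        return self.model.judgments - self.fittedvalues

    def plateau(self, delta: float | None = None) -> tuple[tuple[float, float], tuple[float, float]]:
        """Ranges of (w, beta) whose RSS is within ``delta`` of the minimum.

        The objective is piecewise constant (judgments are integers), so the
        plateau half-width is the honest grid-level uncertainty.  ``delta``
        defaults to one squared judgment point.
        """
        if delta is None:
            delta = 1.0
        near = self.sse_grid <= self.rss + delta
        wi, bi = np.nonzero(near)
        w_rng = (float(self.w_grid[wi].min()), float(self.w_grid[wi].max()))
        b_rng = (float(self.beta_grid[bi].min()), float(self.beta_grid[bi].max()))
        return w_rng, b_rng

    def summary(self) -> str:
        (w_lo, w_hi), (b_lo, b_hi) = self.plateau()
        lines = [
            "Cue-integration judgment model (grid search)",
            "=" * 48,
            f"No. observations:      {self.nobs}",
            f"tolerance tau (px):    {self.model.tolerance_px:g} (fixed)",
            f"cue weight w:          {self.cue_weight:.3f}   plateau [{w_lo:.2f}, {w_hi:.2f}]",
            f"prior self-belief b:   {self.prior_self_belief:.3f}   plateau [{b_lo:.2f}, {b_hi:.2f}]",
            f"residual SS:           {self.rss:.2f}",
            f"RMS residual (points): {np.sqrt(self.rss / self.nobs):.3f}",
        ]
        return "\n".join(lines)


def simulate_fake_trial_indices(
    profile: ParticipantProfile,
    n_trials: int,
    *,
    path: TargetPath | None = None,
    mask_lead_s: float = 0.5,
    mask_tail_s: float = 0.5,
    refresh_hz: float = 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate FAKE trials and return their (prediction error, judgment) pairs.

    Each trial pairs a proprioceptively-controlled pen path with an
    independent visually-controlled replay (the practice-regime kinematics),
    exactly the ingredients of a FAKE trial; horizontal progression is
    beep-locked and identical for both, so the pen-cursor distance reduces to
    the vertical error difference.
    """
    if path is None:
        path = TargetPath()
    if rng is None:
        rng = np.random.default_rng(seed)
    visibility = build_visibility(path, mask_lead_s, mask_tail_s)
    dt = 1.0 / refresh_hz
    n_steps = round(path.duration_s * refresh_hz)
    t = np.arange(n_steps + 1) * dt
    vis = visibility.visible_mask(t)

    pen_gains = np.full(n_steps, profile.proprio_gain)
    replay_gains = np.where(vis[:-1], profile.visual_gain, profile.proprio_gain)
    e_pen = _simulate_error_matrix(profile, pen_gains, dt, n_trials, rng)
    e_rep = _simulate_error_matrix(profile, replay_gains, dt, n_trials, rng)
    d = np.abs(e_pen - e_rep)[:, vis].mean(axis=1)

    s = np.minimum(d / profile.tolerance_px, 1.0)
    latent = 9.0 - 8.0 * (
        profile.cue_weight * s
        + (1.0 - profile.cue_weight) * (1.0 - profile.prior_self_belief)
    )
    if profile.judgment_noise_sigma > 0:
        latent = latent + rng.normal(0.0, profile.judgment_noise_sigma, size=n_trials)
    judgments = np.clip(np.floor(latent + 0.5), 1, 9).astype(int)
    return pd.DataFrame({"mean_pen_cursor_px": d, "judgment": judgments})


def run_recovery_experiment(
    true_profile: ParticipantProfile | None = None,
    n_trials: int = 160,
    n_replicates: int = 100,
    tolerance: float = 0.15,
    *,
    seed: int = 0,
) -> dict:
    """Recover the cue weight from simulated FAKE trials, many times over.

    Returns a dict with the per-replicate estimates and the fraction of
    replicates whose fitted cue weight lies within ``tolerance`` of the
    generating value.
    """
    if true_profile is None:
        true_profile = default_profiles()["pb_like"]
    ss = np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        df = simulate_fake_trial_indices(true_profile, n_trials, rng=rng)
        res = CueIntegrationModel.from_dataframe(df, tolerance_px=true_profile.tolerance_px).fit()
        rows.append(res.params)
    est = pd.DataFrame(rows)
    hit = np.abs(est["cue_weight"] - true_profile.cue_weight) <= tolerance
    return {
        "true_cue_weight": true_profile.cue_weight,
        "estimates": est,
        "success_rate": float(hit.mean()),
        "n_trials": n_trials,
        "n_replicates": n_replicates,
        "tolerance": tolerance,
    }
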