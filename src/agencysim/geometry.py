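"""Canvas, target path, pacing and cursor-visibility geometry.

The task presents a three-cycle sine wave as a target line on a monitor.
Participants trace it with a digitizer pen, paced by beeps that coincide with
the sine extrema at one-second intervals.  The cursor (visual feedback) is
masked during the first cycle plus a short lead into cycle 2 and a short tail
at the end of the last cycle, so that SELF and replayed (FAKE) feedback cannot
be told apart by movement onset/offset timing.

Coordinate convention: origin at the top-left of the canvas, x rightward,
y downward, positions in float pixels.  All intervals are closed-open
``[a, b)``; the single exception is the trial end point, which belongs to the
final mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, PacingError, ScheduleError

__all__ = [
    "CanvasSpec",
    "TargetPath",
    "VisibilitySchedule",
    "BeepSchedule",
    "target_position",
    "build_visibility",
    "build_beeps",
]


@dataclass(frozen=True)
class CanvasSpec:
    """Monitor plotting area and refresh rate.

    Defaults describe a full-HD panel with a 309 x 174 mm plotting area
    refreshed at 60 Hz, matching the apparatus the task was designed for.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_mm: float = 309.0
    height_mm: float = 174.0
    refresh_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm", "refresh_hz"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ConfigurationError(f"CanvasSpec.{name} must be positive and finite, got {v!r}")

    @property
    def px_per_mm(self) -> float:
        return self.width_px / self.width_mm


@dataclass(frozen=True)
class TargetPath:
    """The sine-wave target line with its pacing geometry.

    The pen progresses horizontally at constant speed from ``x_start_px`` to
    ``x_end_px`` over ``n_cycles * cycle_period_s`` seconds while the vertical
    coordinate follows ``y_center + amplitude * sin(2*pi*t / period)``.
    ``x_start_px > x_end_px`` encodes a right-to-left start side.
    """

    n_cycles: int = 3
    cycle_period_s: float = 2.0
    amplitude_px: float = 270.0
    x_start_px: float = 192.0
    x_end_px: float = 1728.0
    y_center_px: float = 540.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigurationError(f"n_cycles must be >= 1, got {self.n_cycles}")
        for name in ("cycle_period_s", "amplitude_px"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ConfigurationError(f"TargetPath.{name} must be positive and finite, got {v!r}")
        for name in ("x_start_px", "x_end_px", "y_center_px"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"TargetPath.{name} must be finite")
        if self.x_start_px == self.x_end_px:
            raise ConfigurationError("x_start_px and x_end_px must differ")

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.cycle_period_s

    @property
    def direction(self) -> str:
        return "left_to_right" if self.x_end_px > self.x_start_px else "right_to_left"

    def y_at_time(self, t):
        """Vertical target coordinate at time ``t`` (scalar or array)."""
        return self.y_center_px + self.amplitude_px * np.sin(
            2.0 * np.pi * np.asarray(t, dtype=float) / self.cycle_period_s
        )

    def y_at_x(self, x):
        """Vertical coordinate of the target *line* at horizontal position ``x``.

        Inverts the constant-speed horizontal progression, so this equals
        ``y_at_time`` for any point actually on the paced path.
        """
        x = np.asarray(x, dtype=float)
        span = self.x_end_px - self.x_start_px
        u = (x - self.x_start_px) / span
        tol = 1e-9
        if np.any(u < -tol) or np.any(u > 1.0 + tol):
            raise ValueError("x outside the horizontal span of the target line")
        t = np.clip(u, 0.0, 1.0) * self.duration_s
        return self.y_at_time(t)


def target_position(path: TargetPath, t):
    """Paced target position ``(x, y)`` at time ``t`` (scalar or array, seconds).

    Raises :class:`ValueError` if any ``t`` falls outside ``[0, duration]``.
    """
    t_arr = np.asarray(t, dtype=float)
    tol = 1e-9
    if np.any(t_arr < -tol) or np.any(t_arr > path.duration_s + tol):
        raise ValueError(f"t outside [0, {path.duration_s}] s")
    t_arr = np.clip(t_arr, 0.0, path.duration_s)
    u = t_arr / path.duration_s
    x = path.x_start_px + (path.x_end_px - path.x_start_px) * u
    y = path.y_at_time(t_arr)
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(x), float(y)
    return x, y


@dataclass(frozen=True)
class VisibilitySchedule:
    """Closed-open masked intervals over one trial.

    A time point is visible iff it lies in ``[0, total_duration_s]`` and in no
    masked interval; the exact trial end point counts as masked when the final
    interval ends there.
    """

    masked_intervals: tuple[tuple[float, float], ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        prev_end = 0.0
        for a, b in self.masked_intervals:
            if not (0.0 <= a < b <= self.total_duration_s):
                raise ScheduleError(f"masked interval [{a}, {b}) outside [0, {self.total_duration_s}]")
            if a < prev_end:
                raise ScheduleError("masked intervals must be disjoint and ordered")
            prev_end = b
        if not self.visible_mask(np.linspace(0.0, self.total_duration_s, 1201)).any():
            raise ScheduleError("masks cover the entire trial; no visible samples remain")

    def is_visible(self, t: float) -> bool:
        return bool(self.visible_mask(t))

    def visible_mask(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        visible = (t >= 0.0) & (t <= self.total_duration_s)
        for a, b in self.masked_intervals:
            visible &= ~((t >= a) & (t < b))
            if b == self.total_duration_s:  # trial end belongs to the tail mask
                visible &= t != b
        return visible

    @property
    def visible_intervals(self) -> tuple[tuple[float, float], ...]:
        """Complement of the masks within ``[0, total_duration_s)``."""
        out = []
        cursor = 0.0
        for a, b in self.masked_intervals:
            if a > cursor:
                out.append((cursor, a))
            cursor = max(cursor, b)
        if cursor < self.total_duration_s:
            out.append((cursor, self.total_duration_s))
        return tuple(out)


def build_visibility(
    path: TargetPath, mask_lead_s: float = 0.5, mask_tail_s: float = 0.5
) -> VisibilitySchedule:
    """Cursor-visibility schedule: cycle 1 plus ``mask_lead_s`` into cycle 2 and
    the final ``mask_tail_s`` are masked.

    With the defaults (3 cycles of 2 s, 0.5 s lead and tail) the cursor is
    visible exactly on ``[2.5 s, 5.5 s)``.
    """
    if mask_lead_s < 0 or mask_tail_s < 0:
        raise ScheduleError("mask lead/tail must be >= 0")
    if mask_lead_s >= path.cycle_period_s or mask_tail_s >= path.cycle_period_s:
        raise ScheduleError("mask lead/tail must be shorter than one cycle")
    duration = path.duration_s
    head_end = path.cycle_period_s + mask_lead_s
    tail_start = duration - mask_tail_s
    if head_end >= tail_start:
        raise ScheduleError("masks cover the entire trial")
    masked: list[tuple[float, float]] = [(0.0, head_end)]
    if mask_tail_s > 0:
        masked.append((tail_start, duration))
    return VisibilitySchedule(tuple(masked), duration)


@dataclass(frozen=True)
class BeepSchedule:
    """Pacing beeps, one per sine extremum."""

    beep_times_s: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.beep_times_s)


def build_beeps(path: TargetPath, strict: bool = True) -> BeepSchedule:
    """Beep times at the sine extrema: ``period/4 + k*period/2``.

    With ``strict=True`` (default) the cycle period must be 2 s so consecutive
    beeps fall exactly 1 s apart, as the pacing requires.
    """
    if strict and path.cycle_period_s != 2.0:
        raise PacingError(
            "beeps at 1-s intervals require a 2-s cycle period; "
            f"got {path.cycle_period_s} s (pass strict=False to allow)"
        )
    p = path.cycle_period_s
    times = tuple(p / 4.0 + k * p / 2.0 for k in range(2 * path.n_cycles))
    return BeepSchedule(times)
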