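"""Optional matplotlib views of score tables and comparison reports."""

from __future__ import annotations

import numpy as np


def plot_judgment_vs_error(scatter, profile=None, ax=None):
    """Scatter of per-trial FAKE prediction error vs self-other judgment.

    ``scatter`` is the ``ComparisonReport.scatter`` frame (or any frame with
    ``mean_pen_cursor_px`` and ``judgment`` columns, optionally ``profile``).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = scatter
    if profile is not None and "profile" in df.columns:
        df = df[df["profile"] == profile]
    ax.scatter(df["mean_pen_cursor_px"], df["judgment"], s=12, alpha=0.5)
    ax.set_xlabel("mean pen-cursor distance (px)")
    ax.set_ylabel("self-other judgment (1 = other, 9 = self)")
    ax.set_yticks(range(1, 10))
    if profile:
        ax.set_title(profile)
    return ax


def plot_movement_by_condition(movement_by_condition, ax=None):
    """Baseline-subtracted movement error per cycle, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, g in movement_by_condition.groupby("condition"):
        ax.plot(g["cycle"], g["baseline_subtracted_px"], marker="o", label=cond)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("cycle")
    ax.set_ylabel("movement error, cycle-1 baseline subtracted (px)")
    ax.legend(title="condition")
    return ax
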