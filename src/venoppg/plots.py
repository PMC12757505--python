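"""Basic visualisations of the group HR response (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .phases import PHASES, PhaseTimeline

_GROUP_STYLE = {"V": dict(color="tab:blue", ls="--"),
                "C": dict(color="tab:brown", ls="-")}


def plot_group_trajectories(series_by_group: dict, path,
                            timeline: PhaseTimeline | None = None):
    """Median +/- IQR normalized-HR trajectory per group.

    ``series_by_group`` maps group ("V"/"C") to a list of
    NormalizedHRSeries sharing the same time grid.
    """
    timeline = timeline or PhaseTimeline()
    fig, ax = plt.subplots(figsize=(8, 4))
    for group, series_list in series_by_group.items():
        stack = np.vstack([s.delta_hr for s in series_list])
        t = series_list[0].times
        med = np.nanmedian(stack, axis=0)
        q1, q3 = np.nanpercentile(stack, [25, 75], axis=0)
        style = _GROUP_STYLE.get(group, {})
        ax.plot(t, med, label=f"{group}-group", **style)
        ax.fill_between(t, q1, q3, alpha=0.2,
                        color=style.get("color"))
    for onset in timeline.movement_onsets:
        ax.axvline(onset, color="k", lw=0.8)
        for edge in (-1, 1):
            ax.axvline(onset + edge * timeline.transition_exclusion_halfwidth,
                       color="r", lw=0.6, ls=":")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized HR (bpm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_phase_distributions(long_table: pd.DataFrame, path):
    """Per-phase distribution of median normalized HR for both groups."""
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.35
    for k, group in enumerate(("C", "V")):
        sub = long_table[long_table["group"] == group]
        data = [sub.loc[sub["phase"] == p, "median_delta_hr"].to_numpy()
                for p in PHASES]
        positions = np.arange(len(PHASES)) + (k - 0.5) * width
        color = _GROUP_STYLE[group]["color"]
        parts = ax.violinplot([d if len(d) else [0.0] for d in data],
                              positions=positions, widths=width,
                              showmeans=True)
        for body in parts["bodies"]:
            body.set_facecolor(color)
            body.set_alpha(0.4)
    ax.set_xticks(np.arange(len(PHASES)), PHASES)
    ax.set_ylabel("median normalized HR (bpm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
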