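"""Tract-profile figures: group mean +/- sd with significant regions shaded."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .group_stats import GROUP_COLUMN, TINNITUS
from .tractometry import ProfileMatrix, znorm

GROUP_COLORS = {"tinnitus": "#c0392b", "control": "#2c3e50"}


def plot_tract_profile(
    profile: ProfileMatrix,
    cohort: pd.DataFrame,
    stat_table: pd.DataFrame | None = None,
    out_path: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Mean +/- sd profile per group along one bundle, clusters shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.2))
    x = np.arange(profile.values.shape[1])
    for group in ("control", "tinnitus"):
        rows = (cohort[GROUP_COLUMN] == group).to_numpy()
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(profile.values[rows], axis=0)
            sd = np.nanstd(profile.values[rows], axis=0)
        color = GROUP_COLORS[group]
        ax.plot(x, mean, color=color, label=group)
        ax.fill_between(x, mean - sd, mean + sd, color=color, alpha=0.18, lw=0)
    if stat_table is not None:
        sub = stat_table[
            (stat_table["bundle"] == profile.bundle_name)
            & stat_table["cluster_id"].notna()
        ]
        for _, cluster in sub.groupby("cluster_id"):
            segs = cluster["segment"].to_numpy()
            ax.axvspan(segs.min() - 0.5, segs.max() + 0.5, color="gold", alpha=0.3)
    ax.set_xlabel("segment along tract")
    ax.set_ylabel(profile.metric_name)
    ax.set_title(profile.bundle_name)
    ax.legend(frameon=False, fontsize=8)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        ax.figure.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_znormed_metrics(
    profiles_by_metric: dict[str, ProfileMatrix],
    cohort: pd.DataFrame,
    out_path: str | Path | None = None,
) -> plt.Axes:
    """Z-scored comparison of several metrics along one bundle (group means)."""
    _, ax = plt.subplots(figsize=(7, 3.2))
    x = None
    styles = ["-", "--", ":"]
    for (metric, prof), ls in zip(profiles_by_metric.items(), styles):
        z = znorm(prof)
        x = np.arange(z.values.shape[1])
        for group in ("control", "tinnitus"):
            rows = (cohort[GROUP_COLUMN] == group).to_numpy()
            label = f"{metric} ({group})" if group == TINNITUS else f"{metric}"
            ax.plot(
                x,
                np.nanmean(z.values[rows], axis=0),
                ls=ls,
                color=GROUP_COLORS[group],
                label=label,
                lw=1.2,
            )
    ax.set_xlabel("segment along tract")
    ax.set_ylabel("z-scored metric")
    ax.legend(frameon=False, fontsize=7, ncols=2)
    if out_path is not None:
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        ax.figure.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
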