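"""Matplotlib panels: subpopulation time series and sweep summaries."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .metrics import SummaryRow, summary_table  # noqa: E402
from .trajectory import Trajectory  # noqa: E402

__all__ = ["plot_timeseries", "plot_totals", "plot_production_vs_burden"]


def plot_timeseries(traj: Trajectory, path: str | Path,
                    groups: dict[str, list[str]] | None = None,
                    logy: bool = True) -> Path:
    """Class (or class-group) abundances over time, plus cumulative production."""
    fig, (ax, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True,
                                  height_ratios=[2, 1])
    if groups:
        frame = traj.grouped(groups)
        for name in groups:
            ax.plot(frame["time"], frame[name], label=name)
    else:
        for j, label in enumerate(traj.labels):
            series = traj.counts[:, j]
            if series.max() > 0:
                ax.plot(traj.time, series, label=label)
    if logy:
        ax.set_yscale("log")
        ax.set_ylim(bottom=1)
    ax.set_ylabel("abundance (cells)")
    ax.legend(fontsize=7, ncol=2)
    ax2.plot(traj.time, traj.cumulative_production, color="k")
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("cumulative production\n(arb. units)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_totals(rows: Sequence[SummaryRow], path: str | Path,
                x: str = "label") -> Path:
    """Total production per scenario with SD error bars."""
    table = summary_table(rows)
    fig, ax = plt.subplots(figsize=(max(5, 0.6 * len(table)), 4))
    ax.bar(table[x], table["total_production_mean"],
           yerr=table["total_production_sd"], capsize=3)
    ax.set_ylabel("total production (arb. units)")
    ax.tick_params(axis="x", rotation=60, labelsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_production_vs_burden(table: pd.DataFrame, path: str | Path,
                              value: str = "total_production_mean",
                              burden: str = "burden",
                              hue: str = "label") -> Path:
    """Sweep panel: production (or duration) versus burden, one line per label."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, sub in table.groupby(hue):
        sub = sub.sort_values(burden)
        ax.plot(sub[burden], sub[value], marker="o", label=str(name))
    ax.set_xlabel("burden (%)")
    ax.set_ylabel(value.replace("_", " "))
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
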