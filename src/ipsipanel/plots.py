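"""Optional matplotlib views of curves and diagnostics (binary-log delta axis)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_curves(curve_df: pd.DataFrame, path: str | None = None):
    """Estimates vs log2(delta) per outcome wave; reference mean/CI as
    dashed/dotted horizontals; non-overlapping deltas highlighted in red."""
    times = sorted(curve_df["outcome_time"].unique())
    fig, axes = plt.subplots(1, len(times), figsize=(4 * len(times), 3.5),
                             sharey=True, squeeze=False)
    for ax, s in zip(axes[0], times):
        sub = curve_df[curve_df["outcome_time"] == s]
        x = np.log2(sub["delta"].to_numpy())
        colors = np.where(sub["flagged"].to_numpy(dtype=bool), "red", "black")
        if sub["ci_low"].notna().any():
            ax.vlines(x, sub["ci_low"], sub["ci_high"], colors=colors, lw=1)
        ax.scatter(x, sub["estimate"], c=colors, s=14, zorder=3)
        ref = sub["reference_mean"].iloc[0]
        ax.axhline(ref, ls="--", color="gray", lw=1)
        ax.set_title(f"outcome wave {s}")
        ax.set_xlabel(r"$\log_2\,\delta$")
    axes[0][0].set_ylabel("intervention mean")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_shifted_summary(summary: pd.DataFrame, path: str | None = None):
    """Mean shifted propensity with its 10th-90th percentile band per wave."""
    times = sorted(summary["t"].unique())
    fig, axes = plt.subplots(1, len(times), figsize=(4 * len(times), 3.5),
                             sharey=True, squeeze=False)
    for ax, t in zip(axes[0], times):
        sub = summary[summary["t"] == t]
        x = np.log2(sub["delta"].to_numpy())
        ax.vlines(x, sub["p10"], sub["p90"], colors="steelblue", lw=1.5)
        ax.scatter(x, sub["mean_q"], marker="x", color="black", zorder=3)
        ax.set_ylim(-0.02, 1.02)
        ax.set_title(f"wave {t}")
        ax.set_xlabel(r"$\log_2\,\delta$")
    axes[0][0].set_ylabel("shifted propensity")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_overlap(diag: pd.DataFrame, t: int, path: str | None = None):
    """Box-style five-number summaries of fitted propensities per stratum/group."""
    strata = list(dict.fromkeys(diag["stratum"]))
    fig, ax = plt.subplots(figsize=(1.2 * len(strata) * 2 + 2, 3.5))
    pos = 0.0
    ticks, labels = [], []
    for s in strata:
        sub = diag[diag["stratum"] == s]
        for g, color in ((0, "tab:blue"), (1, "tab:orange")):
            row = sub[sub["group"] == g].iloc[0]
            if row["n"] > 0:
                ax.vlines(pos, row["min"], row["max"], color=color, lw=1)
                ax.vlines(pos, row["q1"], row["q3"], color=color, lw=5, alpha=0.6)
                ax.scatter([pos], [row["median"]], color=color, zorder=3, s=12)
            ticks.append(pos)
            labels.append(f"{s}\nX{t}={g} ({row['prop']:.0%})")
            pos += 1.0
        pos += 0.6
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel(f"fitted propensity (wave {t})")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_sensitivity(sweep: pd.DataFrame, path: str | None = None):
    """Curve estimates faceted over the fixed residual correlation."""
    rhos = sorted(sweep["rho"].unique())
    times = sorted(sweep["outcome_time"].unique())
    fig, axes = plt.subplots(len(rhos), len(times),
                             figsize=(3.5 * len(times), 2.5 * len(rhos)),
                             sharex=True, sharey=True, squeeze=False)
    for i, rho in enumerate(rhos):
        for j, s in enumerate(times):
            ax = axes[i][j]
            sub = sweep[(sweep["rho"] == rho) & (sweep["outcome_time"] == s)]
            x = np.log2(sub["delta"].to_numpy())
            ax.plot(x, sub["estimate"], "o-", ms=3, lw=0.8, color="black")
            if sub["ci_low"].notna().any():
                ax.fill_between(x, sub["ci_low"], sub["ci_high"], alpha=0.2)
            ax.axhline(sub["reference_mean"].iloc[0], ls="--", color="gray", lw=0.8)
            if i == 0:
                ax.set_title(f"outcome wave {s}", fontsize=9)
            if j == 0:
                ax.set_ylabel(f"rho={rho}", fontsize=8)
            if i == len(rhos) - 1:
                ax.set_xlabel(r"$\log_2\,\delta$")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
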