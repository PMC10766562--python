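"""Per-cluster trajectory panels (convenience output)."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import MoGPResults

__all__ = ["plot_clusters"]


def plot_clusters(
    results: MoGPResults,
    path: str | Path | None = None,
    max_clusters: int = 12,
    t_max: float | None = None,
):
    """Panel per cluster: member visits, posterior mean, 0.95 interval."""
    clusters = results.clusters[:max_clusters]
    ncol = min(4, len(clusters))
    nrow = math.ceil(len(clusters) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow), squeeze=False)
    scale = results.scale
    horizon = t_max or max(
        tr.t[-1] for tr in results.model.trajectories.values()
    )
    grid = np.linspace(0, horizon, 120)
    for ax, cl in zip(axes.flat, clusters):
        mean, var = cl.mean_function(grid)
        sd = np.sqrt(var)
        ax.fill_between(grid, mean - 1.96 * sd, mean + 1.96 * sd, alpha=0.25, lw=0)
        ax.plot(grid, mean, lw=2)
        for sid in cl.member_ids:
            tr = results.model.trajectories[sid]
            ax.plot(tr.t, tr.y, ".-", lw=0.4, ms=2, alpha=0.4, color="gray")
        ax.set_ylim(scale.y_min - 1, scale.y_max + 1)
        ax.set_title(f"cluster {cl.cluster_id} (n={cl.size})", fontsize=8)
    for ax in axes.flat[len(clusters):]:
        ax.axis("off")
    fig.supxlabel("years from symptom onset")
    fig.supylabel(scale.name)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
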