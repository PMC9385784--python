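"""Histogram panels and size-vs-content scatter figures."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .ploidy import FrequencyDistribution, PeakClassEstimate


def plot_histogram_panels(
    dists: dict[str, FrequencyDistribution],
    path: str | Path,
    estimates: dict[str, PeakClassEstimate] | None = None,
) -> None:
    """One frequency-distribution panel per stage; included classes highlighted."""
    n = len(dists)
    ncol = min(3, max(1, n))
    nrow = math.ceil(n / ncol) if n else 1
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax in axes.ravel():
        ax.set_visible(False)
    for ax, (stage, dist) in zip(axes.ravel(), dists.items()):
        ax.set_visible(True)
        width = dist.class_width
        colors = ["0.6"] * len(dist.counts)
        if estimates and stage in estimates:
            lo, hi = estimates[stage].included_class_indices
            for i in range(lo, hi + 1):
                colors[i] = "tab:red"
        ax.bar(dist.centers, dist.counts, width=width * 0.95, color=colors)
        ax.set_title(stage, fontsize=9)
        ax.set_xlabel("DNA content (pg)")
        ax.set_ylabel("nuclei")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_size_content(records: pd.DataFrame, path: str | Path) -> None:
    """Relative nucleus size vs DNA content, coloured by stage."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for stage, grp in records.groupby("stage"):
        ax.scatter(grp["nrs"], grp["pg"], s=6, alpha=0.5, label=stage)
    ax.set_xlabel("relative nucleus size")
    ax.set_ylabel("DNA content (pg)")
    ax.legend(fontsize=7, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
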