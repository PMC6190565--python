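"""Figure output: histogram + density overlays of the non-covered ratios."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .inference import ratio_density
from .types import WEEKDAYS

_METRICS = (("freq_ratio", "Non-covered consumption frequency ratio"),
            ("amount_ratio", "Non-covered consumption amount ratio"))


def plot_ratio_distributions(coverage: pd.DataFrame, path) -> None:
    """Two-panel histogram + boundary-reflected density of the daily ratios."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (metric, title) in zip(axes, _METRICS):
        values = coverage[metric].dropna().to_numpy()
        if len(values) >= 2:
            ax.hist(values, bins=20, range=(0, 1), density=True, alpha=0.5, color="tab:blue")
            grid, dens = ratio_density(values)
            ax.plot(grid, dens, color="tab:red", lw=1.5)
        ax.set_xlabel(title)
        ax.set_ylabel("density")
        ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def plot_weekday_densities(coverage: pd.DataFrame, path) -> None:
    """Per-weekday density curves of both ratios."""
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for ax, (metric, title) in zip(axes, _METRICS):
        for day in WEEKDAYS:
            values = coverage.loc[coverage["weekday"] == day, metric].dropna().to_numpy()
            if len(values) >= 2:
                grid, dens = ratio_density(values)
                ax.plot(grid, dens, lw=1.2, label=day)
        ax.set_xlabel(title)
        ax.set_ylabel("density")
        ax.set_xlim(0, 1)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
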