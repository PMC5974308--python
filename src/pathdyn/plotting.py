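"""Diagnostic plots: predicted vs. observed metabolite trajectories."""

from __future__ import annotations

import numpy as np

from .predict import TrajectoryPrediction
from .timeseries import OmicsTimeSeries

__all__ = ["plot_trajectories"]


def plot_trajectories(
    predicted: TrajectoryPrediction,
    reference: OmicsTimeSeries | None = None,
    metabolites: list[str] | None = None,
    ncols: int = 5,
    ax_size: float = 2.4,
):
    """Small-multiple plot of predicted (and optionally observed) trajectories.

    Returns the matplotlib figure; callers decide whether to show or save.
    """
    import matplotlib.pyplot as plt

    names = list(metabolites or predicted.metabolite_names)
    nrows = int(np.ceil(len(names) / ncols))
    fig, axes = plt.subplots(nrows, ncols,
                             figsize=(ncols * ax_size, nrows * ax_size),
                             squeeze=False, sharex=True)
    for ax, name in zip(axes.ravel(), names):
        ax.plot(predicted.times, predicted.metabolite(name),
                label="predicted", lw=1.5)
        if reference is not None and name in reference.metabolite_names:
            ax.plot(reference.times, reference.metabolite(name), "o--",
                    ms=3, lw=0.8, label="observed")
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("time (h)")
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    axes[0][0].legend(fontsize=7, frameon=False)
    fig.suptitle(f"strain {predicted.strain_id}", fontsize=10)
    fig.tight_layout()
    return fig
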