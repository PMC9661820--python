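"""Quick-look figures for the standard outputs of a run."""

from __future__ import annotations

import matplotlib.pyplot as plt
import numpy as np

from .unmixing import ConcentrationMaps

__all__ = ["plot_threshold_sweep", "plot_dl_distribution", "plot_maps"]


def plot_threshold_sweep(curve, chosen: float | None = None, ax=None):
    """Classified fraction per population versus threshold, with the chosen
    threshold marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["threshold"], curve["frac_positive"], label="full pathway")
    ax.plot(curve["threshold"], curve["frac_control"], label="control")
    if chosen is not None:
        ax.axvline(chosen, color="red", ls="--", label=f"threshold {chosen:g}")
    ax.set_xlabel("limonene intensity threshold")
    ax.set_ylabel("fraction classified limonene-rich")
    ax.legend()
    return ax


def plot_dl_distribution(agg_table, bins: int = 20, ax=None):
    """Distribution of the d/L polar-localization metric (0.5 = midcell,
    1.0 = pole)."""
    if ax is None:
        _, ax = plt.subplots()
    dl = np.asarray(agg_table["dl_ratio"], float)
    ax.hist(dl, bins=bins, range=(0.5, 1.0), edgecolor="black")
    ax.set_xlabel("d/L")
    ax.set_ylabel("aggregates")
    return ax


def plot_maps(maps: ConcentrationMaps, axes=None):
    """One panel per unmixed channel plus the residual-norm image."""
    n = len(maps.names) + 1
    if axes is None:
        _, axes = plt.subplots(1, n, figsize=(3 * n, 3))
    for ax, name, image in zip(axes, maps.names, maps.maps):
        im = ax.imshow(image, cmap="inferno")
        ax.set_title(name)
        ax.axis("off")
        plt.colorbar(im, ax=ax, fraction=0.046)
    axes[-1].imshow(maps.residual_norm, cmap="viridis")
    axes[-1].set_title("residual norm")
    axes[-1].axis("off")
    return axes
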