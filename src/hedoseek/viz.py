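"""Plot helpers for recovery and ROPE reports (confusion heatmap,
true-vs-recovered scatter, posterior density with shaded ROPE and HDI)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .recovery_rope import RopeInterval  # noqa: E402


def plot_confusion(confusion: pd.DataFrame):
    """Heatmap of generating model (rows) vs best-fitting model (columns)."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    m = confusion.to_numpy(float)
    im = ax.imshow(m, cmap="Blues")
    ax.set_xticks(range(len(confusion.columns)), confusion.columns, rotation=45)
    ax.set_yticks(range(len(confusion.index)), confusion.index)
    ax.set_xlabel("best-fitting model")
    ax.set_ylabel("generating model")
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            ax.text(j, i, f"{m[i, j]:g}", ha="center", va="center")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    return fig


def plot_recovery_scatter(pairs: dict[str, pd.DataFrame]):
    """True vs recovered individual parameters, one panel per parameter."""
    k = len(pairs)
    fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 3))
    if k == 1:
        axes = [axes]
    for ax, (name, df) in zip(axes, pairs.items()):
        ax.scatter(df["true"], df["recovered"], s=12, alpha=0.7)
        lims = [min(df.min()), max(df.max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_title(name)
        ax.set_xlabel("true")
        ax.set_ylabel("recovered")
    fig.tight_layout()
    return fig


def plot_posterior_rope(samples: np.ndarray, rope: RopeInterval,
                        hdi_interval: tuple[float, float], name: str = ""):
    """Posterior density with shaded ROPE (red) and 95% HDI (grey)."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.hist(samples, bins=60, density=True, color="steelblue", alpha=0.8)
    ax.axvspan(rope.lower, rope.upper, color="red", alpha=0.2, label="ROPE")
    ax.axvspan(hdi_interval[0], hdi_interval[1], color="grey", alpha=0.3,
               label="95% HDI")
    ax.set_title(name)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig
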