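"""Diagnostic plots: posterior corner plots and species index distributions."""
from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .inference import PosteriorResult


def corner_plot(result: PosteriorResult, bins: int = 30):
    """Weighted marginal histograms and pairwise density cuts, with the
    maximum-likelihood mode marked by crosses."""
    names = list(result.param_names)
    ndim = len(names)
    fig, axes = plt.subplots(ndim, ndim, figsize=(2.2 * ndim, 2.2 * ndim))
    axes = np.atleast_2d(axes)
    w = result.weights
    for i in range(ndim):
        for j in range(ndim):
            ax = axes[i, j]
            if j > i:
                ax.set_visible(False)
                continue
            xi = result.samples[:, j]
            if i == j:
                ax.hist(xi, bins=bins, weights=w, color="steelblue", histtype="stepfilled")
                ax.axvline(result.mode[names[j]], color="navy", ls="--", lw=1)
            else:
                yi = result.samples[:, i]
                ax.hist2d(xi, yi, bins=bins, weights=w, cmap="Blues")
                ax.plot(result.mode[names[j]], result.mode[names[i]], "+", color="navy", ms=10)
            if i == ndim - 1:
                ax.set_xlabel(names[j])
            if j == 0 and i > 0:
                ax.set_ylabel(names[i])
    fig.suptitle(f"{result.model} posterior ({result.recording_id})")
    fig.tight_layout()
    return fig


def tag_distribution_plot(comparison: dict):
    """Per-species Normal(mu, sqrt(sigma_pop)) curves, musical in blue,
    non-musical in red."""
    fig, ax = plt.subplots(figsize=(7, 4))
    grid = np.linspace(0, 4, 400)
    colors = {"musical": "tab:blue", "non-musical": "tab:red"}
    for group, curves in comparison["curves"].items():
        for c in curves:
            sd = max(c["sd"], 1e-3)
            dens = np.exp(-0.5 * ((grid - c["mean"]) / sd) ** 2) / (np.sqrt(2 * np.pi) * sd)
            ax.plot(grid, dens, color=colors[group], alpha=0.6, lw=1.2)
    ax.set_xlabel(r"spectral index $\beta$")
    ax.set_ylabel("density")
    handles = [plt.Line2D([], [], color=c, label=g) for g, c in colors.items()]
    ax.legend(handles=handles)
    fig.tight_layout()
    return fig
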