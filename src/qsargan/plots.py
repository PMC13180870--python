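"""Optional plot files mirroring the usual fidelity/training figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

_COLORS = {"real": "tab:blue", "synthetic": "tab:orange"}


def _scatter_by_source(ax, coords: pd.DataFrame, xcol: str, ycol: str) -> None:
    for source, group in coords.groupby("source"):
        ax.scatter(group[xcol], group[ycol], s=12, alpha=0.6,
                   label=source, color=_COLORS.get(source))
    ax.legend()


def plot_overlay(coords: pd.DataFrame, path, kind: str = "pca") -> None:
    """Scatter a pca_overlay / tsne_overlay coordinate table to a file."""
    xcol, ycol = ("pc1", "pc2") if kind == "pca" else ("tsne1", "tsne2")
    fig, ax = plt.subplots(figsize=(5, 4))
    _scatter_by_source(ax, coords, xcol, ycol)
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loss_history(history: pd.DataFrame, path) -> None:
    """Generator/discriminator loss curves across epochs."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(history["epoch"], history["g_loss"], label="generator")
    ax.plot(history["epoch"], history["d_loss"], label="discriminator")
    ax.set_xlabel("epoch")
    ax.set_ylabel("BCE loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_descriptor_histograms(real: pd.DataFrame, synthetic: pd.DataFrame,
                               descriptors: list[str], path) -> None:
    """Side-by-side real/synthetic histograms for selected descriptors."""
    n = len(descriptors)
    fig, axes = plt.subplots(1, n, figsize=(3.5 * n, 3))
    if n == 1:
        axes = [axes]
    for ax, d in zip(axes, descriptors):
        ax.hist(real[d], bins=20, alpha=0.5, density=True, label="real",
                color=_COLORS["real"])
        ax.hist(synthetic[d], bins=20, alpha=0.5, density=True, label="synthetic",
                color=_COLORS["synthetic"])
        ax.set_title(d)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
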