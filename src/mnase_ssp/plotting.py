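"""Thin matplotlib renderers for the stored matrices and profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_vplot", "plot_profile", "plot_heatmap", "plot_shift_heatmap"]


def plot_vplot(vplot, path, title: str = "") -> None:
    """Render a V-plot matrix (midpoint offset × fragment length)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    counts = vplot.counts.to_numpy().T
    ax.imshow(
        counts,
        origin="lower",
        aspect="auto",
        extent=[vplot.offsets[0], vplot.offsets[-1], vplot.lengths[0], vplot.lengths[-1]],
        cmap="viridis",
    )
    ax.set_xlabel("midpoint offset from dyad (bp)")
    ax.set_ylabel("fragment length (bp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_profile(profiles, path, title: str = "") -> None:
    """Overlay metagene profiles; ``profiles`` is {label: Series}."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for label, series in profiles.items():
        ax.plot(series.index, series.to_numpy(), label=label, lw=1)
    ax.set_xlabel("offset from anchor (bp)")
    ax.set_ylabel("mean normalized coverage")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "", diverging: bool = False) -> None:
    """Render a per-gene occupancy (or difference) heatmap."""
    fig, ax = plt.subplots(figsize=(6, 5))
    arr = matrix.to_numpy()
    if diverging:
        vmax = np.nanpercentile(np.abs(arr), 99) or 1.0
        kw = {"cmap": "RdBu_r", "vmin": -vmax, "vmax": vmax}
    else:
        kw = {"cmap": "viridis"}
    ax.imshow(arr, aspect="auto", interpolation="nearest",
              extent=[matrix.columns[0], matrix.columns[-1], len(matrix), 0], **kw)
    ax.set_xlabel("offset from +1 dyad (bp)")
    ax.set_ylabel("genes (ranked by length)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_shift_heatmap(result, path, title: str = "") -> None:
    """Median ΔZ per (nucleosome index × rotational position), asterisks on
    significant cells."""
    t = result.table
    pivot = t.pivot(index="nuc_index", columns="position", values="median_dz")
    sig = t.pivot(index="nuc_index", columns="position", values="significant")
    fig, ax = plt.subplots(figsize=(6, 4))
    vmax = np.nanmax(np.abs(pivot.to_numpy())) or 1.0
    ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            if bool(sig.iloc[i, j]):
                ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    ax.set_xticks(range(pivot.shape[1]), pivot.columns)
    ax.set_yticks(range(pivot.shape[0]), [f"+{k}" for k in pivot.index])
    ax.set_xlabel("rotational position (bp)")
    ax.set_ylabel("nucleosome index")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
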