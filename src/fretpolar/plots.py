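"""Figure output: pseudocolor ratio previews, origin-aligned track plots,
polar histograms and heat maps.

All writers save PNG with a null Date entry so repeated runs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .motility import Trajectory
from .polarity import HeatmapMatrix
from .protrusions import PolarHistogram
from .ratio import RatioImage

_SAVE = {"dpi": 120, "metadata": {"Date": None}}


def save_ratio_preview(path: str | Path, ratio: RatioImage,
                       cmap: str = "jet") -> None:
    """8-bit pseudocolor rendering of a ratio image; undefined pixels black."""
    fig, ax = plt.subplots(figsize=(5, 5))
    shown = np.where(ratio.defined_mask, ratio.values, np.nan)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    im = ax.imshow(shown, cmap=cm)
    fig.colorbar(im, ax=ax, label="normalized ratio")
    ax.set_axis_off()
    fig.savefig(path, **_SAVE)
    plt.close(fig)


def plot_tracks(path: str | Path, tracks: list[Trajectory]) -> None:
    """Origin-aligned migration tracks (every track starts at (0, 0))."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for track in tracks:
        rel = track.positions - track.positions[0]
        ax.plot(rel[:, 0], rel[:, 1], lw=1)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.savefig(path, **_SAVE)
    plt.close(fig)


def plot_polar_histogram(path: str | Path, hist: PolarHistogram) -> None:
    """Half-rose plot of protrusion-migration angles over [0, 180] deg."""
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="polar")
    centers = np.radians((hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2)
    widths = np.radians(np.diff(hist.bin_edges))
    ax.bar(centers, hist.frequencies if hist.normalized else hist.counts,
           width=widths, bottom=0.0, edgecolor="black", alpha=0.8)
    ax.set_thetamin(0)
    ax.set_thetamax(180)
    fig.savefig(path, **_SAVE)
    plt.close(fig)


def plot_heatmap(path: str | Path, heatmap: HeatmapMatrix,
                 cmap: str = "viridis") -> None:
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(4, len(heatmap.rows))))
    im = ax.imshow(heatmap.values, aspect="auto", cmap=cmap,
                   extent=(heatmap.columns[0], heatmap.columns[-1],
                           len(heatmap.rows), 0))
    ax.set_yticks(np.arange(len(heatmap.rows)) + 0.5)
    ax.set_yticklabels(heatmap.rows, fontsize=6)
    ax.set_xlabel("time (min)")
    fig.colorbar(im, ax=ax, label=heatmap.quantity)
    fig.savefig(path, **_SAVE)
    plt.close(fig)
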