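"""Optional report figures (requires matplotlib).

Kept deliberately thin: each function takes objects the analysis modules
already produce and returns a matplotlib Figure; callers decide the format.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import LinkageMap
from .relatedness import TrioDistances, trifurcation_coordinates
from .scan import ScanResult


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_trifurcation(distances: list[TrioDistances]):
    """Star plots of parental relatedness: three branch vectors per scope at
    120 degree spacing, branch length = distance to the trifurcation point."""
    plt = _plt()
    n = len(distances)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 2.4), squeeze=False)
    for ax, d in zip(axes[0], distances):
        for parent, (x, y) in trifurcation_coordinates(d).items():
            ax.plot([0, x], [0, y], "-", lw=2)
            ax.annotate(parent, (x, y), ha="center", va="center")
        lim = max(d.dBt, d.dEt, d.dKt) * 1.3 + 1e-6
        ax.set_xlim(-lim, lim); ax.set_ylim(-lim, lim)
        ax.set_aspect("equal"); ax.axis("off")
        ax.set_title(str(d.scope), fontsize=8)
    return fig


def plot_cm_vs_mb(lmap: LinkageMap, anchors: pd.DataFrame):
    """Marker map position (cM) against physical position (Mb) per LG."""
    plt = _plt()
    a = anchors.set_index("marker") if "marker" in anchors.columns else anchors
    lgs = sorted(lmap.table["LG"].unique())
    fig, axes = plt.subplots(1, len(lgs), figsize=(2.2 * len(lgs), 2.6),
                             squeeze=False, sharey=False)
    for ax, lg in zip(axes[0], lgs):
        sub = lmap.table[lmap.table["LG"] == lg]
        bp = sub["marker"].map(a["bp"]) / 1e6
        ax.plot(sub["cM"], bp, ".", ms=2)
        ax.set_title(f"LG {lg}", fontsize=8)
        ax.set_xlabel("cM"); ax.set_ylabel("Mb")
    fig.tight_layout()
    return fig


def plot_t_scan(result: ScanResult, lmap: LinkageMap, scope: str = "pooled"):
    """Student's t against map position per LG for one scan scope."""
    plt = _plt()
    pos = lmap.table.set_index("marker")
    t = result.table[result.table["scope"] == scope].dropna(subset=["t"])
    t = t.join(pos[["LG", "cM"]], on="marker").dropna(subset=["cM"])
    lgs = sorted(t["LG"].unique())
    fig, axes = plt.subplots(1, max(len(lgs), 1), figsize=(2.4 * max(len(lgs), 1), 2.6),
                             squeeze=False, sharey=True)
    for ax, lg in zip(axes[0], lgs):
        sub = t[t["LG"] == lg]
        ax.plot(sub["cM"], sub["t"], ".", ms=2)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(f"LG {lg}", fontsize=8)
        ax.set_xlabel("cM")
    axes[0][0].set_ylabel("Student's t")
    fig.tight_layout()
    return fig


def plot_crossover_histogram(counts: pd.DataFrame):
    """Frequency distribution of junction counts per RIL, per LG."""
    plt = _plt()
    lgs = list(counts.columns)
    fig, axes = plt.subplots(1, len(lgs), figsize=(2.0 * len(lgs), 2.4),
                             squeeze=False, sharey=True)
    for ax, lg in zip(axes[0], lgs):
        col = counts[lg].dropna().astype(int)
        top = int(col.max()) if len(col) else 1
        ax.hist(col, bins=np.arange(-0.5, top + 1.5))
        ax.set_title(f"LG {lg}", fontsize=8)
        ax.set_xlabel("crossovers per RIL")
    fig.tight_layout()
    return fig
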