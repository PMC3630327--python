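"""Best-effort figure rendering: enrichment bar panels and co-occupancy
heatmaps with dendrograms.

Figures mirror the tabular reports; they carry no information the TSV/JSON
outputs lack and are excluded from bit-stability guarantees.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .combinatorial import CombinatorialResult
from .enrichment import GscaReport

__all__ = ["gsca_figure", "cgsca_figure"]


def gsca_figure(report: GscaReport, path: str | Path) -> None:
    """Bar panel of -log10 corrected p per dataset; significant datasets
    highlighted in gold."""
    results = report.results
    heights = [-np.log10(max(r.p_corrected, 1e-300)) for r in results]
    colors = ["gold" if r.significant else "0.7" for r in results]
    labels = [f"{r.tf} ({r.dataset_id})" for r in results]
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(results)), 4))
    ax.bar(range(len(results)), heights, color=colors, edgecolor="0.3", linewidth=0.5)
    alpha = report.parameters.get("alpha", 0.001)
    ax.axhline(-np.log10(alpha), color="crimson", linestyle="--", linewidth=1,
               label=f"alpha = {alpha:g}")
    ax.set_xticks(range(len(results)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10}$ corrected $p$")
    ax.set_title(f"GSCA: {report.query}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cgsca_figure(result: CombinatorialResult, path: str | Path) -> None:
    """Dendrogram over datasets on top of the binary co-occupancy heatmap,
    columns in dendrogram leaf order."""
    order = result.dendrogram.leaf_order()
    ids = [result.matrix.dataset_ids[i] for i in order]
    X = result.matrix.values[:, order]
    fig, (ax_top, ax_hm) = plt.subplots(
        2, 1, figsize=(max(5, 0.6 * len(ids)), 7),
        gridspec_kw={"height_ratios": [1, 3]},
    )
    _draw_dendrogram(result, order, ax_top)
    ax_hm.imshow(X, aspect="auto", cmap="Greys", interpolation="nearest")
    ax_hm.set_xticks(range(len(ids)))
    ax_hm.set_xticklabels(ids, rotation=90, fontsize=8)
    ax_hm.set_ylabel(f"{X.shape[0]} regions (bound by >= 2 datasets)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _draw_dendrogram(result: CombinatorialResult, order: list[int], ax) -> None:
    dendro = result.dendrogram
    K = dendro.n_leaves
    xpos = {leaf: order.index(leaf) for leaf in range(K)}
    height = {leaf: 0.0 for leaf in range(K)}
    for t in range(len(dendro.merges)):
        a, b, h = int(dendro.merges[t, 0]), int(dendro.merges[t, 1]), float(dendro.merges[t, 2])
        xa, xb = xpos[a], xpos[b]
        ha, hb = height[a], height[b]
        ax.plot([xa, xa, xb, xb], [ha, h, h, hb], color="0.2", linewidth=1)
        node = K + t
        xpos[node] = (xa + xb) / 2
        height[node] = h
    ax.set_xlim(-0.5, K - 0.5)
    ax.set_xticks([])
    ax.set_ylabel("1 - r")
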