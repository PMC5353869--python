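"""Heatmap rendering of correspondence maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .correspondence import CorrespondenceMap

__all__ = ["plot_map"]


def plot_map(cmap: CorrespondenceMap, path: str | Path, title: str = "") -> None:
    """Render a correspondence map as a heatmap with a -log10(p) color scale."""
    scores = cmap.scores[cmap.row_order][:, cmap.col_order]
    rows = [cmap.row_labels[i] for i in cmap.row_order]
    cols = [cmap.col_labels[j] for j in cmap.col_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(cols) + 2), max(3, 0.25 * len(rows) + 1.5))
    )
    im = ax.imshow(scores, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rows)), rows, fontsize=6)
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label=r"mapping score $-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "exoncorr"})
    plt.close(fig)
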