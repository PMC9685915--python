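"""Minimal figures: a three-set Venn diagram with region counts.

Drawn with plain matplotlib circles; the counts come from
:func:`lowph.response.venn_analysis`, so the figure is a rendering of the
exact set arithmetic, not a separate computation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .response import VennSummary

# circle centres/radius for a symmetric 3-set layout, and the canonical
# position of each of the 7 exclusive regions in that layout
_CENTRES = {0: (0.38, 0.62), 1: (0.62, 0.62), 2: (0.50, 0.40)}
_RADIUS = 0.22
_REGION_XY = {
    (0,): (0.28, 0.70), (1,): (0.72, 0.70), (2,): (0.50, 0.30),
    (0, 1): (0.50, 0.68), (0, 2): (0.38, 0.47), (1, 2): (0.62, 0.47),
    (0, 1, 2): (0.50, 0.53),
}


def plot_venn3(summary: VennSummary, path: str | Path, title: str = "") -> None:
    if len(summary.set_names) != 3:
        raise ValueError("plot_venn3 requires exactly three sets")
    fig, ax = plt.subplots(figsize=(4, 4))
    colors = ["#1b9e77", "#d95f02", "#7570b3"]
    for i, name in enumerate(summary.set_names):
        ax.add_patch(
            Circle(_CENTRES[i], _RADIUS, alpha=0.3, color=colors[i], lw=1.5, ec="black")
        )
        x, y = _CENTRES[i]
        ax.text(x, y + _RADIUS + 0.04, name, ha="center", fontsize=10)
    for combo, (x, y) in _REGION_XY.items():
        key = frozenset(summary.set_names[i] for i in combo)
        ax.text(x, y, str(len(summary.regions[key])), ha="center", va="center", fontsize=9)
    ax.set_xlim(0, 1)
    ax.set_ylim(0.1, 1)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=11)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
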