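"""Frontier scatter plots in criteria space (2D and 3D).

Genes are plotted at their transformed (minimisation) criteria values, so
the origin is the ideal point and solutions toward it are more
significant; an option flips back to raw |difference| axes for
interpretability.  Plotting is a pure consumer: it never alters an
analysis result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .dataset import ValidationError  # noqa: E402
from .pareto import CriteriaMatrix, FrontierAssignment  # noqa: E402


@dataclass
class PlotSpec:
    """What to draw: which criteria columns, which frontiers, labels, output."""

    axes: tuple[int, ...] = (0, 1)
    highlight_frontiers: tuple[int, ...] = (1,)
    annotate_frontier_1: bool = False
    raw_axes: bool = False
    out_path: str = "mco_frontiers.png"
    dpi: int = 150

    def __post_init__(self) -> None:
        if len(self.axes) not in (2, 3):
            raise ValidationError("plots are 2D or 3D: choose 2 or 3 criteria axes")


def plot_frontiers(
    cm: CriteriaMatrix, fa: FrontierAssignment, spec: PlotSpec
) -> str:
    """Scatter all genes, highlighting the requested frontiers; returns the path."""
    if set(map(str, fa.gene_ids)) != set(map(str, cm.gene_ids)):
        raise ValidationError("assignment and criteria matrix must share gene ids")
    for ax_idx in spec.axes:
        if not 0 <= ax_idx < cm.C:
            raise ValidationError(
                f"axis {ax_idx} out of range for a {cm.C}-criteria matrix"
            )
    pos = {g: i for i, g in enumerate(cm.gene_ids)}
    order = np.array([pos[g] for g in fa.gene_ids], dtype=int)
    coords = cm.criteria[order][:, list(spec.axes)]
    labels = [cm.column_labels()[i] for i in spec.axes]
    if spec.raw_axes:
        coords = cm.criteria.max(axis=0)[list(spec.axes)][None, :] - coords
        labels = [f"|difference| ({lab})" for lab in labels]

    three_d = len(spec.axes) == 3
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d" if three_d else None)
    fidx = fa.frontier_index

    background = fidx == 0
    if background.any():
        ax.scatter(*coords[background].T, s=8, c="lightgrey", label="unranked")
    ranked_not_high = (fidx > 0) & ~np.isin(fidx, spec.highlight_frontiers)
    if ranked_not_high.any():
        ax.scatter(*coords[ranked_not_high].T, s=10, c="tab:blue", alpha=0.6,
                   label="other frontiers")
    cmap = plt.get_cmap("autumn")
    n_high = max(len(spec.highlight_frontiers), 1)
    for j, f in enumerate(sorted(spec.highlight_frontiers)):
        sel = fidx == f
        if not sel.any():
            continue
        ax.scatter(*coords[sel].T, s=28, color=cmap(j / n_high), edgecolors="black",
                   linewidths=0.4, label=f"frontier {f}")
    if spec.annotate_frontier_1 and not three_d:
        for g, xy in zip(fa.gene_ids[fidx == 1], coords[fidx == 1]):
            ax.annotate(str(g), xy, fontsize=7, xytext=(2, 2),
                        textcoords="offset points")

    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    if three_d:
        ax.set_zlabel(labels[2])
    origin = "origin = largest change" if not spec.raw_axes else "origin = no change"
    ax.set_title(f"Pareto-efficient frontiers ({origin})")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(spec.out_path, dpi=spec.dpi)
    plt.close(fig)
    return spec.out_path
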