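"""Rendering: star-coordinates LDA scatter plots with feature axis vectors.

The plot shows every sample of a cohort projected to the plane, colored by
class, with the per-feature axis vectors drawn from the origin.  Long
vectors pointing toward a class's side of the plot mark the features whose
presence drives samples there — the visual cue guiding split selection.
Only the longest vectors are labeled to keep the plot readable.

Output is deterministic for fixed inputs (seeded jitter, fixed SVG hash
salt, no embedded dates), so figures are reproducible artifacts.
"""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cohort import Cohort
from .projection import ProjectionModel, sc_project
from .tree import DEFAULT_CLASS_COLORS, _FALLBACK_CYCLE

__all__ = ["render_sc_plot"]


def _class_color_map(classes, class_colors):
    if class_colors is not None:
        missing = [c for c in classes if c not in class_colors]
        if missing:
            raise ValueError(f"missing color for class(es): {missing}")
        return dict(class_colors)
    cmap = {}
    for i, c in enumerate(classes):
        cmap[c] = DEFAULT_CLASS_COLORS.get(c, _FALLBACK_CYCLE[i % len(_FALLBACK_CYCLE)])
    return cmap


def render_sc_plot(
    model: ProjectionModel,
    cohort: Cohort,
    path,
    class_colors: dict | None = None,
    top_labels: int = 10,
    min_length_percentile: float = 0.0,
    vector_scale: float = 1.0,
    title: str | None = None,
) -> str:
    """Write the SC/LDA scatter with axis vectors to an SVG or PNG file.

    Samples are projected with the model and colored by class; axis vectors
    are drawn from the origin, with labels only for the ``top_labels``
    longest (clutter control) and vectors below the ``min_length_percentile``
    length percentile suppressed entirely.  With two classes only one
    discriminant direction exists: points fall on a horizontal strip and a
    small deterministic ordinate jitter keeps them legible.
    """
    if cohort.schema.names != model.feature_names:
        raise ValueError("model and cohort feature schemas differ")
    matplotlib.rcParams["svg.hashsalt"] = "sctree"
    P = sc_project(model, cohort.X)
    one_dim = np.allclose(model.axis_vectors[:, 1], 0.0)
    if one_dim:
        jitter_rng = np.random.default_rng(0)
        span = max(float(np.ptp(P[:, 0])), 1.0)
        P = P.copy()
        P[:, 1] = jitter_rng.uniform(-0.02 * span, 0.02 * span, size=P.shape[0])

    cmap = _class_color_map(sorted(np.unique(cohort.y).tolist()), class_colors)
    fig, ax = plt.subplots(figsize=(7, 6))
    for c in sorted(cmap):
        mask = cohort.y == c
        if mask.any():
            ax.scatter(P[mask, 0], P[mask, 1], s=12, alpha=0.55, color=cmap[c],
                       label=str(c), linewidths=0)

    lengths = np.linalg.norm(model.axis_vectors, axis=1)
    cutoff = np.percentile(lengths, min_length_percentile) if min_length_percentile > 0 else 0.0
    label_set = set(np.argsort(-lengths)[:top_labels])
    for i, name in enumerate(model.feature_names):
        if lengths[i] <= max(cutoff, 1e-12):
            continue
        vx, vy = model.axis_vectors[i] * vector_scale
        ax.annotate("", xy=(vx, vy), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="0.25", lw=1.1))
        if i in label_set:
            ax.annotate(name, xy=(vx, vy), xytext=(vx * 1.06, vy * 1.06),
                        fontsize=8, color="0.15")

    ax.axhline(0, color="0.85", lw=0.6, zorder=0)
    ax.axvline(0, color="0.85", lw=0.6, zorder=0)
    ax.set_xlabel("discriminant axis 1")
    ax.set_ylabel("discriminant axis 2" if not one_dim else "jitter (2-class strip)")
    ax.legend(loc="best", fontsize=8, frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)
    return str(path)
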