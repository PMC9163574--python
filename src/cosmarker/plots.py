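"""Diagnostic figures: scatter simplex, marker heatmap and null-fit overlay.

Plots are pure side outputs; they never modify numeric results.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .nulls import FnmNull, MgCall
from .preprocess import SubtypeProfile

__all__ = ["mg_heatmap", "null_fit_plot", "simplex_scatter"]


def simplex_scatter(profile: SubtypeProfile, calls: list[MgCall], path: str | Path) -> None:
    """Scatter of unit-normalized subtype patterns on the simplex face.

    Each feature's mean pattern s_i is projected to s_i/||s_i|| and drawn
    on the face spanned by the first three subtypes (for K > 3 the
    remaining coordinates are dropped before projection); accepted markers
    are colored by their assigned subtype, ideal references sit at the
    vertices.
    """
    s = profile.means[:, :3] if len(profile.subtypes) > 3 else profile.means
    if s.shape[1] == 2:
        s = np.column_stack([s, np.zeros(len(s))])
    norms = np.linalg.norm(s, axis=1)
    norms[norms == 0] = 1.0
    u = s / norms[:, None]
    # barycentric -> 2-D equilateral-triangle coordinates
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    bary = u / u.sum(axis=1, keepdims=True)
    xy = bary @ verts

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xy[:, 0], xy[:, 1], s=4, c="0.75", label="all features")
    shown = profile.subtypes[:3]
    cmap = plt.get_cmap("tab10")
    accepted = {c.feature: c.k_hat for c in calls if c.accepted}
    for ci, k in enumerate(shown):
        idx = [i for i, f in enumerate(profile.features) if accepted.get(f) == k]
        if idx:
            ax.scatter(xy[idx, 0], xy[idx, 1], s=8, color=cmap(ci), label=f"MG {k}")
    ax.scatter(verts[:, 0], verts[:, 1], marker="^", color="k", s=60, label="ideal MG")
    ax.set_axis_off()
    ax.legend(loc="upper right", fontsize=7)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def mg_heatmap(profile: SubtypeProfile, calls: list[MgCall], path: str | Path) -> None:
    """Row-normalized heatmap of accepted markers, grouped by subtype."""
    accepted = sorted((c for c in calls if c.accepted), key=lambda c: (c.k_hat, -c.t))
    if not accepted:
        raise ValueError("no accepted markers to draw")
    idx = {f: i for i, f in enumerate(profile.features)}
    rows = profile.means[[idx[c.feature] for c in accepted]]
    rows = rows / rows.max(axis=1, keepdims=True)

    fig, ax = plt.subplots(figsize=(4, max(2, 0.02 * len(rows))))
    ax.imshow(rows, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(profile.subtypes)), profile.subtypes, fontsize=7)
    ax.set_yticks([])
    ax.set_xlabel("subtype")
    ax.set_ylabel(f"{len(rows)} accepted MG")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def null_fit_plot(scores: np.ndarray, null: FnmNull, path: str | Path) -> None:
    """Score histogram with the fitted finite-normal-mixture density overlaid."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(scores, bins=80, density=True, color="0.8", label="scores")
    grid = np.linspace(min(scores), max(scores), 400)
    ax.plot(grid, null.pdf(grid), "r-", lw=1.5, label=f"FNM ({null.n_components} comp.)")
    ax.set_xlabel("cosine score")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
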