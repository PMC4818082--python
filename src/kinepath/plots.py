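"""Figures: per-group average reach paths and DFD learning curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Circle

from .analysis import ReferencePaths
from .metrics import NoMovementError, average_paths, segment_movement, time_normalize
from .synth import ExperimentDataset

__all__ = ["figure_average_paths", "figure_learning_curves", "save_figure"]

_GROUP_COLORS = {1: "#d62728", 2: "#1f77b4", 3: "#2ca02c"}


def save_figure(fig: Figure, path) -> None:
    FigureCanvasAgg(fig)
    fig.savefig(path, dpi=150)


def figure_average_paths(
    dataset: ExperimentDataset,
    references: ReferencePaths,
    block: int | None = None,
    n_samples: int = 100,
) -> Figure:
    """Average last-block trajectories per group, with both reference paths.

    One panel per group; per ordered target pair the time-normalized trial
    paths are averaged and drawn with a shaded band of pointwise 95 %
    confidence half-widths, over the straight (dotted) and least-energy
    (dashed) references.
    """
    block = block if block is not None else dataset.config.blocks
    objects = {s.label: s.haptic_object for s in dataset.specs}
    labels = sorted(objects)
    fig = Figure(figsize=(4 * len(labels), 4))
    axes = fig.subplots(1, len(labels), sharex=True, sharey=True)
    axes = np.atleast_1d(axes)
    for ax, label in zip(axes, labels):
        by_pair: dict = {}
        for tr in dataset:
            if tr.group != label or tr.block != block:
                continue
            try:
                seg = segment_movement(tr.trajectory)
                by_pair.setdefault((tr.start_target, tr.end_target), []).append(
                    time_normalize(seg, n=n_samples)
                )
            except NoMovementError:
                continue
        for pair, paths in sorted(by_pair.items()):
            mean, half = average_paths(paths)
            pts = mean.points
            width = np.linalg.norm(half, axis=1)[: pts.shape[0]]
            tang = np.gradient(pts, axis=0)
            nrm = np.linalg.norm(tang, axis=1, keepdims=True)
            nrm[nrm == 0] = 1.0
            normal = np.column_stack([-tang[:, 1], tang[:, 0]]) / nrm
            band_lo = pts - width[:, None] * normal
            band_hi = pts + width[:, None] * normal
            poly = np.vstack([band_lo, band_hi[::-1]])
            ax.fill(poly[:, 0], poly[:, 1], color=_GROUP_COLORS.get(label, "gray"),
                    alpha=0.15, lw=0)
            ax.plot(pts[:, 0], pts[:, 1], color=_GROUP_COLORS.get(label, "gray"), lw=1.5)
            s_ref = references.straight(pair).points
            e_ref = references.energy(pair, objects[label]).points
            ax.plot(s_ref[:, 0], s_ref[:, 1], "k:", lw=0.8)
            ax.plot(e_ref[:, 0], e_ref[:, 1], "k--", lw=0.8)
        for i in range(dataset.layout.n_targets):
            c = dataset.layout.center(i)
            ax.add_patch(
                Circle(c, dataset.layout.diameter / 2, fill=False, color="k", lw=0.8)
            )
        ax.set_title(f"Group {label} ({objects[label].replace('_', ' ')} haptics)")
        ax.set_aspect("equal")
        ax.set_xlabel("x (m)")
    axes[0].set_ylabel("y (m)")
    fig.tight_layout()
    return fig


def figure_learning_curves(group_summary: pd.DataFrame) -> Figure:
    """Block-by-block group means of both DFD metrics with 95 % error bars."""
    fig = Figure(figsize=(9, 4))
    ax_s, ax_e = fig.subplots(1, 2, sharex=True)
    for metric, ax, title in (
        ("dfd_straight", ax_s, "DFD from straight path"),
        ("dfd_energy", ax_e, "DFD from least-energy path"),
    ):
        for label, sub in group_summary.groupby("group"):
            sub = sub.sort_values("block")
            ax.errorbar(
                sub["block"], 1e3 * sub[metric], yerr=1e3 * sub[f"{metric}_ci"],
                label=f"Group {label}", color=_GROUP_COLORS.get(label, "gray"),
                marker="o", ms=3, capsize=2, lw=1.2,
            )
        ax.set_xlabel("block")
        ax.set_ylabel("DFD (mm)")
        ax.set_title(title)
    ax_s.legend(frameon=False)
    fig.tight_layout()
    return fig
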