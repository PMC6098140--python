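"""Figure analogues of the standard visualisations: per-hen location
rasters, per-variable box plots, annotated dendrograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from .cluster import Grouping, LinkageTree
from .core import ZONE_NAMES, ZONES, HenDay
from .features import SummaryFeatures, feature_table

__all__ = ["plot_location", "plot_boxes", "plot_dendrogram"]


def plot_location(hendays: list[HenDay], path) -> None:
    """Location raster for one hen: one row per day, zone vs time of day."""
    if not hendays:
        raise ValueError("need at least one hen-day")
    hen_ids = {hd.hen_id for hd in hendays}
    if len(hen_ids) != 1:
        raise ValueError(f"expected one hen, got {sorted(hen_ids)}")
    hendays = sorted(hendays, key=lambda hd: hd.day_index)
    n = len(hendays)
    fig, axes = plt.subplots(n, 1, figsize=(10, 1.1 * n), sharex=True, squeeze=False)
    for ax, hd in zip(axes[:, 0], hendays):
        t = (np.arange(hd.n_samples) + hd.window.start_s) / 3600.0
        ax.step(t, hd.series, where="post", lw=0.6)
        ax.set_ylim(0.5, 5.5)
        ax.set_yticks(list(ZONES))
        ax.set_ylabel(f"day {hd.day_index}", rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("time of day (h)")
    fig.suptitle(f"hen {hendays[0].hen_id}: zone occupancy")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)


def plot_boxes(features: list[SummaryFeatures], path) -> None:
    """Six panels (five zones + total): one box per hen."""
    if not features:
        raise ValueError("need at least one hen-day")
    df = feature_table(features)
    hens = sorted(df["hen_id"].unique(), key=lambda h: (len(h), h))
    panels = [f"z{z}" for z in ZONES] + ["total"]
    titles = [f"Zone {z} ({ZONE_NAMES[z]})" for z in ZONES] + ["Total transitions"]
    fig, axes = plt.subplots(2, 3, figsize=(13, 7))
    for ax, var, title in zip(axes.ravel(), panels, titles):
        data = [df.loc[df["hen_id"] == h, var].to_numpy() for h in hens]
        ax.boxplot(data, tick_labels=hens)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("hen")
        ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_dendrogram(tree: LinkageTree, grouping: Grouping, path) -> None:
    """Dendrogram with the chosen groups outlined; hen-days placed outside
    their hen's best group are marked with an asterisk."""
    n = tree.n_leaves
    if n < 2:
        raise ValueError("dendrogram needs at least two leaves")

    from .cluster import score_grouping, split_label

    # best group per hen, to flag misplaced hen-days
    report = score_grouping(grouping, list(tree.labels))
    best: dict[str, int] = {}
    for hen in [s.hen_id for s in report.scores]:
        days = {
            lbl: grouping.assignment[lbl]
            for lbl in tree.labels
            if split_label(lbl)[0] == hen
        }
        counts: dict[int, int] = {}
        for g in days.values():
            counts[g] = counts.get(g, 0) + 1
        top = max(counts.values())
        best[hen] = min(g for g, c in counts.items() if c == top)

    fig, ax = plt.subplots(figsize=(max(8, 0.16 * n), 5))
    dn = dendrogram(
        tree.merges, labels=tree.labels, ax=ax, leaf_font_size=6, no_plot=False
    )
    order = dn["ivl"]
    for pos, lbl in enumerate(order):
        hen = split_label(lbl)[0]
        if grouping.assignment[lbl] != best[hen]:
            ax.annotate(
                "*",
                (10 * pos + 5, 0),
                color="red",
                ha="center",
                va="top",
                fontsize=10,
                annotation_clip=False,
            )
    # outline contiguous stretches of each group along the leaf order
    ymax = float(tree.heights.max())
    pos = 0
    while pos < n:
        g = grouping.assignment[order[pos]]
        end = pos
        while end + 1 < n and grouping.assignment[order[end + 1]] == g:
            end += 1
        ax.add_patch(
            plt.Rectangle(
                (10 * pos + 1, 0),
                10 * (end - pos + 1) - 2,
                0.35 * ymax,
                fill=False,
                edgecolor="C0",
                lw=0.8,
            )
        )
        pos = end + 1
    ax.set_ylabel("merge height")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
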