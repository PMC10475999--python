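"""Figures summarising a pipeline run.

Three views: the steady-state responses per accession (gs, E, A, iWUE
against VPD), the segmented-fit parameter space (breakpoint against the
slopes, with cluster hulls), and the cluster map on the first two
principal components.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["fig_steady_responses", "fig_breakpoint_slopes", "fig_clusters",
           "write_figures"]

_CLUSTER_COLORS = ["#1b7837", "#762a83", "#d95f02", "#386cb0", "#666666"]


def fig_steady_responses(steady: pd.DataFrame):
    """Accession mean +/- se of gs, E, A and iWUE against realized VPD."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    labels = {"gs": "gs (mol m$^{-2}$ s$^{-1}$)",
              "e": "E (mmol m$^{-2}$ s$^{-1}$)",
              "a": "A ($\\mu$mol m$^{-2}$ s$^{-1}$)",
              "iwue": "iWUE ($\\mu$mol mol$^{-1}$)"}
    ok = steady.loc[~steady["missing"]]
    for ax, col in zip(axes.ravel(), labels):
        for acc, grp in ok.groupby("accession"):
            agg = grp.groupby("level").agg(
                vpd=("vpd", "mean"), m=(col, "mean"), se=(col, "sem"))
            ax.errorbar(agg["vpd"], agg["m"], yerr=agg["se"], marker="o",
                        ms=3, lw=1, capsize=2, label=acc)
        ax.set_ylabel(labels[col])
    for ax in axes[1]:
        ax.set_xlabel("VPD (kPa)")
    axes[0, 0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    return fig


def _hull(ax, pts, color):
    if len(pts) >= 3:
        from scipy.spatial import ConvexHull
        hull = ConvexHull(pts)
        poly = pts[np.append(hull.vertices, hull.vertices[0])]
        ax.plot(poly[:, 0], poly[:, 1], color=color, lw=1)
        ax.fill(poly[:, 0], poly[:, 1], color=color, alpha=0.12)
    elif len(pts) == 2:
        ax.plot(pts[:, 0], pts[:, 1], color=color, lw=1)


def fig_breakpoint_slopes(seg: pd.DataFrame, assignments: pd.Series | None = None,
                          title: str = ""):
    """Breakpoint vs slope before (left) and after (right), with SE bars."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, slope_col in zip(axes, ("slope_before", "slope_after")):
        for _, row in seg.iterrows():
            cl = (int(assignments.get(row["accession"], 0))
                  if assignments is not None else 0)
            color = _CLUSTER_COLORS[cl % len(_CLUSTER_COLORS)]
            ax.errorbar(row[slope_col], row["psi"],
                        xerr=row.get(f"{slope_col}_se", np.nan),
                        yerr=row.get("psi_se", np.nan),
                        marker="o", ms=4, color=color, capsize=2)
            ax.annotate(row["accession"], (row[slope_col], row["psi"]),
                        fontsize=6, xytext=(3, 3), textcoords="offset points")
        if assignments is not None:
            for cl in sorted(assignments.unique()):
                accs = assignments.index[assignments == cl]
                sub = seg[seg["accession"].isin(accs)]
                pts = sub[[slope_col, "psi"]].to_numpy(dtype=float)
                _hull(ax, pts, _CLUSTER_COLORS[int(cl) % len(_CLUSTER_COLORS)])
        ax.set_xlabel(f"{slope_col.replace('_', ' ')} (per kPa)")
    axes[0].set_ylabel("breakpoint $\\psi$ (kPa)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def fig_clusters(scores: pd.DataFrame, assignments: pd.Series,
                 explained: np.ndarray | None = None):
    """Accessions on the first two principal components, hulls per cluster."""
    fig, ax = plt.subplots(figsize=(6, 5))
    for cl in sorted(assignments.unique()):
        accs = assignments.index[assignments == cl]
        pts = scores.loc[accs, ["PC1", "PC2"]].to_numpy(dtype=float)
        color = _CLUSTER_COLORS[int(cl) % len(_CLUSTER_COLORS)]
        ax.scatter(pts[:, 0], pts[:, 1], color=color, label=f"group {cl}")
        _hull(ax, pts, color)
        for a, (px, py) in zip(accs, pts):
            ax.annotate(str(a), (px, py), fontsize=6,
                        xytext=(3, 3), textcoords="offset points")
    if explained is not None and len(explained) >= 2:
        ax.set_xlabel(f"PC1 ({100 * explained[0]:.0f}% var)")
        ax.set_ylabel(f"PC2 ({100 * explained[1]:.0f}% var)")
    else:
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def write_figures(results: dict, out_dir) -> list[str]:
    """Render the standard figure set from :func:`run_pipeline` output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    assignments = results["clusters"].assignments
    jobs = [
        ("steady_responses.png", fig_steady_responses(results["steady"])),
        ("segmented_leaf.png",
         fig_breakpoint_slopes(results["seg_leaf"], assignments, "leaf")),
        ("segmented_whole_plant.png",
         fig_breakpoint_slopes(results["seg_wp"], assignments, "whole plant")),
        ("clusters_pca.png",
         fig_clusters(results["pca_scores"], assignments,
                      results["explained_variance"])),
    ]
    for name, fig in jobs:
        path = out / name
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(str(path))
    return written
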