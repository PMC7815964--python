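"""SVG figure rendering for exploration and model-evaluation outputs.

All figures are written as scalable vector graphics so they can go
straight into a manuscript.  Matplotlib's Agg backend is forced so the
functions work headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from .explore import ClusteringResult, CorrelationResult
from .features import ImportanceTable


def save_correlation_heatmap(result: CorrelationResult, path: str | Path) -> None:
    mat = result.matrix
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(mat)), max(4, 0.3 * len(mat))))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat)), labels=mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(mat)), labels=mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{result.method} r")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def save_dendrogram(result: ClusteringResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(result.labels)), 4))
    dendrogram(result.merge_matrix, labels=result.labels, ax=ax, leaf_font_size=6)
    ax.set_ylabel(f"{result.distance} distance ({result.linkage} linkage)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def save_importance_bars(table: ImportanceTable, path: str | Path, top: int = 20) -> None:
    ordered = table.table.sort_values("score", ascending=True, kind="stable").tail(top)
    fig, ax = plt.subplots(figsize=(5, max(3, 0.25 * len(ordered))))
    ax.barh(ordered["feature"], ordered["score"], color="#4878a8")
    ax.set_xlabel("importance (0-100)")
    ax.set_title(f"{table.algorithm_id} ({table.method})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def save_roc_curves(curves: dict[str, list], path: str | Path) -> None:
    """curves maps a label -> list of (threshold, fpr, tpr) points."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for label, points in curves.items():
        fpr = [p[1] for p in points]
        tpr = [p[2] for p in points]
        ax.plot(fpr, tpr, label=label, lw=1.2)
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
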