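"""Diagnostic plots: sample PCA and a z-score expression heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .de_test import zscore_cluster
from .expression_norm import NormalizedMatrix


def pca_plot(normalized: NormalizedMatrix, design: pd.DataFrame, path: str | Path) -> None:
    """Sample PCA on log-transformed normalized values, colored by condition.

    Used as an outlier screen only; no sample is removed automatically.
    """
    values = np.log1p(normalized.values.to_numpy(dtype=float)).T  # samples x genes
    centered = values - values.mean(axis=0, keepdims=True)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt[:2].T
    var_frac = s[:2] ** 2 / (s**2).sum()
    fig, ax = plt.subplots(figsize=(5, 4))
    conditions = design["condition"]
    for cond in dict.fromkeys(conditions):
        sel = (conditions == cond).to_numpy()
        ax.scatter(coords[sel, 0], coords[sel, 1], label=cond, s=40)
    ax.set_xlabel(f"PC1 ({100 * var_frac[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * var_frac[1]:.0f}%)")
    ax.legend(title="condition", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def zscore_heatmap(normalized: NormalizedMatrix, path: str | Path) -> None:
    """Per-gene z-score heatmap with samples in clustered leaf order."""
    clust = zscore_cluster(normalized)
    z = clust.zscores[clust.leaf_order]
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(clust.leaf_order)))
    ax.set_xticklabels(clust.leaf_order, rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
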