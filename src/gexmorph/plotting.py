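"""Minimal figures: the rho distribution and a gene-map scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_rho_distribution(rho, thresholds: dict | None = None, path=None):
    """Histogram of gene-wise Spearman rho with percentile cutoffs."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(np.asarray(rho, float), bins=40, color="steelblue", alpha=0.85)
    if thresholds:
        for key in ("rho_lo", "rho_hi"):
            ax.axvline(thresholds[key], color="crimson", linestyle="--",
                       linewidth=1)
    ax.set_xlabel(r"Spearman $\rho$ (gene vs. GMV-difference map)")
    ax.set_ylabel("genes")
    fig.tight_layout()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_gene_scatter(expr_row, diff_map, gene: str = "", path=None):
    """Regional expression of one gene against the GMV-difference summary."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(np.asarray(diff_map, float), np.asarray(expr_row, float),
               s=18, color="steelblue")
    ax.set_xlabel("regional |t| of GMV group difference")
    ax.set_ylabel(f"{gene} regional expression" if gene else "regional expression")
    fig.tight_layout()
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
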