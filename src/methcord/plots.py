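"""Diagnostic plots: beta-value density and MDS of M-values.

Quick visual QC, not part of the statistical pipeline: density plots show
the bimodal methylation landscape and any batch separation; the MDS plot
(classical scaling of sample-to-sample M-value distances) shows whether
tissue is the dominant source of variance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .io import SampleSheet
from .preprocess import MethylationMatrix

_TISSUE_COLORS = {"bone": "tab:red", "blood": "tab:blue"}


def beta_density_plot(beta: MethylationMatrix, sheet: SampleSheet,
                      path: str | Path) -> None:
    """One density trace per sample, coloured by tissue."""
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0.001, 0.999, 200)
    table = sheet.table.set_index("sample_id")
    for sample in beta.values.columns:
        vals = beta.values[sample].to_numpy()
        kde = _gaussian_kde(vals, grid)
        ax.plot(grid, kde, color=_TISSUE_COLORS[table.loc[sample, "tissue"]],
                alpha=0.5, lw=0.8)
    ax.set_xlabel("beta value")
    ax.set_ylabel("density")
    ax.set_title("Per-sample beta-value densities (red: bone, blue: blood)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _gaussian_kde(x: np.ndarray, grid: np.ndarray) -> np.ndarray:
    from scipy.stats import gaussian_kde
    return gaussian_kde(x)(grid)


def mds_plot(m: MethylationMatrix, sheet: SampleSheet, path: str | Path) -> None:
    """Classical multidimensional scaling of pairwise sample distances."""
    y = m.values.to_numpy().T  # samples x sites
    yc = y - y.mean(axis=0, keepdims=True)
    # principal coordinates via SVD of the centred data matrix
    u, sv, _ = np.linalg.svd(yc, full_matrices=False)
    coords = u[:, :2] * sv[:2]
    table = sheet.table.set_index("sample_id").loc[m.values.columns]
    fig, ax = plt.subplots(figsize=(6, 5))
    for tissue, color in _TISSUE_COLORS.items():
        mask = (table["tissue"] == tissue).to_numpy()
        ax.scatter(coords[mask, 0], coords[mask, 1], c=color, label=tissue)
    for i, sample in enumerate(m.values.columns):
        ax.annotate(str(table.loc[sample, "subject_id"]),
                    (coords[i, 0], coords[i, 1]), fontsize=6)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.legend()
    ax.set_title("MDS of M-values")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def permutation_histogram(null_counts: np.ndarray, observed: int,
                          path: str | Path) -> None:
    """Null distribution of the SMP count with the observed count marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(null_counts, bins=40, color="gray", edgecolor="none")
    ax.axvline(observed, color="tab:red", lw=2,
               label=f"observed = {observed}")
    ax.set_xlabel("SMP-passing count per permutation")
    ax.set_ylabel("iterations")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
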