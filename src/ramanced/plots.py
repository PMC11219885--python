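"""Presentation-only figures for the exploratory stage.

Each function writes one image file and returns its path; numerical
content is produced by :mod:`ramanced.explore` and tested there.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .explore import PCAResult, VariabilityProfile

__all__ = ["plot_pca_scores", "plot_variability", "plot_mean_spectra", "plot_roc"]


def plot_pca_scores(pca: PCAResult, labels: np.ndarray, path: str | Path) -> Path:
    """Score scatter in the first two components, colored by class."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = np.asarray(labels)
    for value, name, color in ((1, "CeD", "tab:red"), (0, "control", "tab:blue")):
        sel = labels == value
        ax.scatter(pca.scores[sel, 0], pca.scores[sel, 1], s=18, label=name, c=color)
    r = pca.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({100 * r[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * r[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_variability(
    profile: VariabilityProfile, wavenumbers: np.ndarray, path: str | Path
) -> Path:
    """Per-wavenumber SD plus first two loading profiles, stacked."""
    path = Path(path)
    fig, axes = plt.subplots(3, 1, figsize=(7, 6), sharex=True)
    axes[0].plot(wavenumbers, profile.wavenumber_sd, lw=0.8)
    axes[0].set_ylabel("SD")
    axes[1].plot(wavenumbers, profile.pc1_contribution, lw=0.8)
    axes[1].set_ylabel("PC1 loading")
    axes[2].plot(wavenumbers, profile.pc2_contribution, lw=0.8)
    axes[2].set_ylabel("PC2 loading")
    axes[2].set_xlabel("wavenumber (cm$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_mean_spectra(
    wavenumbers: np.ndarray,
    matrix: np.ndarray,
    labels: np.ndarray,
    path: str | Path,
) -> Path:
    """Class-mean spectra overlaid."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = np.asarray(labels)
    for value, name, color in ((1, "CeD", "tab:red"), (0, "control", "tab:blue")):
        ax.plot(wavenumbers, matrix[labels == value].mean(axis=0), label=name, c=color, lw=0.9)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_roc(curves: dict[str, np.ndarray], path: str | Path) -> Path:
    """One or more ROC curves (FPR, TPR) on the chance diagonal."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for name, curve in curves.items():
        ax.plot(curve[:, 0], curve[:, 1], label=name, lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
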