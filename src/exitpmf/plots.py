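"""Figures regenerated from the written data files (never from memory)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_pmf", "plot_profile_heatmap", "plot_match_heatmap"]


def plot_pmf(tsv_paths, png_path, labels=None) -> None:
    """Free-energy profiles (one or more profile TSVs) on one axis."""
    if isinstance(tsv_paths, (str, bytes)) or hasattr(tsv_paths, "__fspath__"):
        tsv_paths = [tsv_paths]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for i, p in enumerate(tsv_paths):
        d = pd.read_csv(p, sep="\t", comment="#", header=None,
                        names=["d", "f", "err"])
        lab = labels[i] if labels else str(p)
        ax.plot(d["d"], d["f"], label=lab)
        if np.isfinite(d["err"]).any():
            ax.fill_between(d["d"], d["f"] - d["err"], d["f"] + d["err"], alpha=0.25)
    ax.set_xlabel("ligand : pocket-COM distance (Å)")
    ax.set_ylabel("free energy (kcal/mol)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


def plot_profile_heatmap(tsv_path, png_path) -> None:
    """Per-residue interaction-energy profile heatmap (residues × distance)."""
    d = pd.read_csv(tsv_path, sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(6, 0.25 * len(d) + 1.5))
    vmax = np.nanmax(np.abs(d.values)) or 1.0
    im = ax.imshow(d.values, aspect="auto", cmap="RdYlGn_r", vmin=-vmax, vmax=vmax,
                   extent=[float(d.columns[0]), float(d.columns[-1]), len(d), 0])
    ax.set_yticks(np.arange(len(d)) + 0.5, d.index, fontsize=6)
    ax.set_xlabel("exit coordinate (Å)")
    fig.colorbar(im, ax=ax, label="interaction energy (kcal/mol)")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


def plot_match_heatmap(tsv_path, png_path) -> None:
    """Quasi-mode × normal-mode Mantel-r heatmap."""
    d = pd.read_csv(tsv_path, sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(d.values, aspect="auto", cmap="viridis", vmin=-1, vmax=1)
    ax.set_xlabel("normal mode")
    ax.set_ylabel("quasi-mode")
    fig.colorbar(im, ax=ax, label="Mantel r")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
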