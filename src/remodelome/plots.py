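"""Optional figure output: diversity/mortality overlay, cluster
trajectories, PCA projections.  All acceptance-relevant numbers live in
the TSV bundle; these files are for eyes only."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def diversity_overlay(results, path: Path) -> None:
    """Detected-feature counts with cubic trend and survivorship."""
    fig, axes = plt.subplots(1, len(results.diets), figsize=(9, 3.5), sharey=True)
    for ax, diet in zip(np.atleast_1d(axes), results.diets):
        sub = results.diversity[results.diversity["diet"] == diet]
        ax.plot(sub["age_days"], sub["detected_count"], "^", color="tab:red", ms=5)
        coeffs = results.diversity_trends[diet]["cubic_coeffs"]
        grid = np.linspace(sub["age_days"].min(), sub["age_days"].max(), 200)
        ax.plot(grid, np.polyval(coeffs, grid), color="tab:red", lw=1.5)
        ax.set_title(diet)
        ax.set_xlabel("age (d)")
        ax2 = ax.twinx()
        ax2.set_ylim(0, 1.05)
    np.atleast_1d(axes)[0].set_ylabel("detected features")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cluster_trajectories(results, path: Path) -> None:
    if results.cluster_trajectories is None:
        return
    diets = results.diets
    k = results.cluster_set.k
    ncol = 4
    nrow = int(np.ceil(k / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), sharex=True)
    for cid, ax in zip(range(1, k + 1), axes.ravel()):
        for diet, style in zip(diets, ("-", "--")):
            m = results.cluster_trajectories[diet]
            ax.plot(m.columns, m.loc[cid], style, label=diet)
        n = int(results.cluster_set.sizes()[cid])
        ax.set_title(f"cluster {cid} (n={n})", fontsize=8)
    axes.ravel()[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_projections(results, path: Path) -> None:
    if results.pca is None:
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, mode in zip(axes, ("across_diets", "within_diet")):
        entry = results.pca[mode]
        sc_ = entry["scores"]
        for diet, marker in zip(results.diets, ("s", "^")):
            sub = sc_[sc_["diet"] == diet]
            ax.scatter(sub["PC1"], sub["PC2"], c=sub["age_days"], cmap="viridis",
                       marker=marker, label=diet, s=35)
        evr = entry["explained_variance_ratio"]
        ax.set_xlabel(f"PC1 ({100 * evr[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * evr[1]:.0f}%)")
        ax.set_title(mode.replace("_", " "))
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_all(results, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    diversity_overlay(results, outdir / "diversity.png")
    cluster_trajectories(results, outdir / "cluster_trajectories.png")
    pca_projections(results, outdir / "pca.png")
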