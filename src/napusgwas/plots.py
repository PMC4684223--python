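"""Manhattan / QQ / predictive-ability plots (file export only)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan(results: pd.DataFrame, path, p_threshold: float | None = None) -> None:
    """Manhattan plot: chromosomes concatenated on x, -log10 p on y."""
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(results.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p_value"]), s=4, color="C0" if i % 2 == 0 else "C1")
        ticks.append(offset + grp["pos"].max() / 2)
        labels.append(str(chrom))
        offset += grp["pos"].max()
    if p_threshold is not None:
        ax.axhline(-np.log10(p_threshold), ls="--", color="k", lw=0.8)
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq(p_values, path) -> None:
    """QQ plot of observed vs expected -log10 p under the uniform null."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.scatter(exp, -np.log10(p), s=4)
    lim = max(exp.max(), -np.log10(p).max())
    ax.plot([0, lim], [0, lim], color="k", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ability_grid(summary: pd.DataFrame, path) -> None:
    """Mean predictive ability vs training fraction, one line per marker panel."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for mode, grp in summary.groupby("mode", sort=False):
        grp = grp.sort_values("fraction")
        ax.errorbar(grp["fraction"], grp["mean_ability"], yerr=grp["sd_ability"], label=mode, marker="o")
    ax.set_xlabel("training fraction")
    ax.set_ylabel("predictive ability (r)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
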