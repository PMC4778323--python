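"""Metagene panel plots (optional, behind the CLI ``--plots`` flag)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metagene import BinningConfig, MetageneResult


def plot_metagene_panels(result: MetageneResult, cfg: BinningConfig, path: str | Path) -> None:
    """One panel per gene class: sense (black) and antisense (grey) ratios.

    Vertical guides mark the TSS and pA anchors of the scaled abscissa.
    """
    labels = []
    for p in result.profiles:
        if p.class_label not in labels:
            labels.append(p.class_label)
    ncols = 2
    nrows = -(-len(labels) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(9, 3 * nrows), squeeze=False, sharex=True)
    x = range(cfg.n_bins)
    for i, label in enumerate(labels):
        ax = axes[i // ncols][i % ncols]
        sense = result.get(label, "sense")
        anti = result.get(label, "antisense")
        ax.plot(x, sense.bins, color="black", label="sense")
        ax.plot(x, anti.bins, color="grey", label="antisense")
        for anchor in (cfg.flank_units, cfg.flank_units + cfg.body_units):
            ax.axvline(anchor, color="tab:red", lw=0.8, ls="--")
        ax.axhline(1.0, color="0.8", lw=0.8)
        ax.set_title(f"{label} (n={sense.n_genes})")
        ax.set_ylabel("mutant / WT ratio")
    for j in range(len(labels), nrows * ncols):
        axes[j // ncols][j % ncols].axis("off")
    axes[0][0].legend(frameon=False)
    for ax in axes[-1]:
        ax.set_xlabel("metagene abscissa (units)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
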