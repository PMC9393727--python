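"""Diagnostic plots: the nine-quadrant map and top-term bar chart."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .enrichment import top_terms  # noqa: E402


def quadrant_plot(association: pd.DataFrame, path, rna_thr: float = 1.0,
                  prot_thr: float = math.log2(1.5)) -> Path:
    """Scatter of RNA vs protein log2FC with the 3x3 threshold grid.

    Genes meeting both omics' significance criteria are drawn in red,
    echoing the convention of marking "met the P-value" genes.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    sig = association["rna_significant"] & association["prot_significant"]
    ax.scatter(association.loc[~sig, "rna_log2fc"],
               association.loc[~sig, "prot_log2fc"], s=6, c="grey", alpha=0.5)
    ax.scatter(association.loc[sig, "rna_log2fc"],
               association.loc[sig, "prot_log2fc"], s=8, c="red")
    for v in (-rna_thr, rna_thr):
        ax.axvline(v, lw=0.8, ls="--", c="black")
    for h in (-prot_thr, prot_thr):
        ax.axhline(h, lw=0.8, ls="--", c="black")
    ax.set_xlabel("RNA log2 fold change")
    ax.set_ylabel("protein log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def enrichment_barplot(results: pd.DataFrame, path, n: int = 20,
                       alpha: float = 0.05) -> Path:
    """Horizontal bars of -log10 adjusted p for the top N terms."""
    top = top_terms(results, n).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * max(len(top), 4) + 1.2))
    ax.barh(top.index, -np.log10(top["adjusted"].clip(lower=1e-300)),
            color="steelblue")
    ax.axvline(-math.log10(alpha), color="gold", lw=1.5)
    ax.set_xlabel("-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
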