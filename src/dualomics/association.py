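"""Transcriptome-proteome association: Venn accounting and the
nine-quadrant concordance map.

Genes measured in both omics layers are placed on a 3x3 grid by their
RNA log2 fold change (x axis, threshold 1) and protein log2 fold change
(y axis, threshold log2 1.5).  Cells are numbered row-major from the
top-left::

        prot up    1 | 2 | 3
        prot  ~    4 | 5 | 6
        prot dn    7 | 8 | 9
                  dn   ~   up   (RNA)

so quadrant 3 is concordant up-regulation, quadrant 7 concordant
down-regulation and quadrant 5 unchanged in both layers.  Values landing
exactly on a threshold fall to the middle band (strict inequalities).
Genes without a protein measurement are excluded, not placed in
quadrant 5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rna import STATUS_NS

PROT_THRESHOLD_DEFAULT = math.log2(1.5)


def assign_quadrant(rna_log2fc: float, prot_log2fc: float,
                    rna_thr: float = 1.0,
                    prot_thr: float = PROT_THRESHOLD_DEFAULT) -> int:
    """Quadrant 1-9 of one (RNA, protein) log2 fold-change pair."""
    if not (np.isfinite(rna_log2fc) and np.isfinite(prot_log2fc)):
        raise ValueError("both log2 fold changes must be finite")
    col = 0 if rna_log2fc < -rna_thr else (2 if rna_log2fc > rna_thr else 1)
    row = 0 if prot_log2fc > prot_thr else (2 if prot_log2fc < -prot_thr else 1)
    return 3 * row + col + 1


def assign_quadrants(rna_log2fc, prot_log2fc, rna_thr: float = 1.0,
                     prot_thr: float = PROT_THRESHOLD_DEFAULT) -> np.ndarray:
    """Vectorized :func:`assign_quadrant`."""
    x = np.asarray(rna_log2fc, dtype=float)
    y = np.asarray(prot_log2fc, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("both log2 fold changes must be finite")
    col = np.where(x < -rna_thr, 0, np.where(x > rna_thr, 2, 1))
    row = np.where(y > prot_thr, 0, np.where(y < -prot_thr, 2, 1))
    return 3 * row + col + 1


@dataclass(frozen=True)
class VennSummary:
    """Two-set overlap with the shared percentage of the union."""

    n_a: int
    n_b: int
    n_common: int
    pct_shared: float


def venn_overlap(set_a, set_b) -> VennSummary:
    """Overlap accounting of two feature-ID sets.

    The shared percentage is 100 * |A n B| / |A u B|, rounded to two
    decimals; an empty union yields 0.0.
    """
    a, b = set(set_a), set(set_b)
    common = len(a & b)
    union = len(a | b)
    pct = round(100.0 * common / union, 2) if union else 0.0
    return VennSummary(n_a=len(a), n_b=len(b), n_common=common, pct_shared=pct)


def _clean_mapping(gene2protein: pd.DataFrame) -> pd.DataFrame:
    mapping = gene2protein[["gene", "protein"]]
    if mapping.duplicated().any():
        warnings.warn("duplicate gene-protein mapping rows dropped", stacklevel=3)
        mapping = mapping.drop_duplicates()
    conflicts = mapping["gene"][mapping["gene"].duplicated()].unique().tolist()
    if conflicts:
        raise ValueError(f"genes mapped to multiple proteins: {conflicts[:5]}")
    return mapping


def associate(rna_results: pd.DataFrame, prot_results: pd.DataFrame,
              gene2protein: pd.DataFrame, rna_thr: float = 1.0,
              prot_thr: float = PROT_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Join one contrast's RNA and protein results gene by gene.

    Returns one row per gene measured (with finite fold changes) in both
    layers: ``rna_log2fc, rna_significant, prot_log2fc,
    prot_significant, quadrant``.  Significance flags are the full
    per-omics DE criteria carried in each result's ``status`` column.
    """
    mapping = _clean_mapping(gene2protein)
    mapping = mapping[mapping["gene"].isin(rna_results.index)
                      & mapping["protein"].isin(prot_results.index)]
    if mapping.empty:
        return pd.DataFrame(columns=["rna_log2fc", "rna_significant",
                                     "prot_log2fc", "prot_significant",
                                     "quadrant"])
    rna = rna_results.loc[mapping["gene"]]
    prot = prot_results.loc[mapping["protein"]]
    out = pd.DataFrame({
        "rna_log2fc": rna["log2fc"].to_numpy(),
        "rna_significant": (rna["status"] != STATUS_NS).to_numpy(),
        "prot_log2fc": prot["log2fc"].to_numpy(),
        "prot_significant": (prot["status"] != STATUS_NS).to_numpy(),
    }, index=pd.Index(mapping["gene"], name="gene"))
    defined = np.isfinite(out["rna_log2fc"]) & np.isfinite(out["prot_log2fc"])
    out = out[defined]
    out["quadrant"] = assign_quadrants(out["rna_log2fc"], out["prot_log2fc"],
                                       rna_thr, prot_thr)
    return out


def quadrant_counts(association: pd.DataFrame) -> pd.DataFrame:
    """Per-quadrant totals with the doubly-significant subtotal.

    ``significant`` counts genes meeting both omics' significance
    criteria (the "met the P-value" subset); ``not_significant`` the
    remainder.  All nine quadrants are reported even when empty.
    """
    rows = []
    for q in range(1, 10):
        sub = association[association["quadrant"] == q]
        sig = int((sub["rna_significant"] & sub["prot_significant"]).sum())
        rows.append({"quadrant": q, "total": len(sub), "significant": sig,
                     "not_significant": len(sub) - sig})
    return pd.DataFrame(rows).set_index("quadrant")


def concordant_significant_genes(association: pd.DataFrame) -> set[str]:
    """Doubly-significant genes in the concordant quadrants (3 and 7)."""
    m = (association["quadrant"].isin([3, 7])
         & association["rna_significant"] & association["prot_significant"])
    return set(association.index[m])
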