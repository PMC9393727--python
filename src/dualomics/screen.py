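"""Cross-genotype differential-response screen.

For each candidate gene the screen compares the salt-induced fold
change in the overexpressor line with that in the wild type, per omics
layer:

    delta = log2( FC(OX 24h/0h) / FC(WT 24h/0h) )

computed at the RNA level (FC2/FC1) and at the protein level (FC4/FC3).
A gene passes when |delta| > 1 (strictly) at either level.  When a
level lacks evidence (a missing or non-positive fold change) its delta
is undefined and the screen is evaluated on the remaining level only.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .association import concordant_significant_genes

SCREEN_COLUMNS = ["fc1", "fc2", "delta_rna", "fc3", "fc4", "delta_prot",
                  "pass_rna", "pass_prot", "pass_any"]


def differential_response(fc_control: float, fc_treatment: float) -> float:
    """log2 ratio of two fold changes; NaN when either is unusable.

    ``fc_control`` is the wild-type response fold change, ``fc_treatment``
    the overexpressor's.  Non-positive or missing inputs yield NaN (the
    level is recorded as lacking evidence, not raised).
    """
    if fc_control is None or fc_treatment is None:
        return math.nan
    if not (np.isfinite(fc_control) and np.isfinite(fc_treatment)):
        return math.nan
    if fc_control <= 0 or fc_treatment <= 0:
        return math.nan
    return math.log2(fc_treatment / fc_control)


def build_screen_table(fc_table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Screen records from a table of four fold-change columns.

    ``fc_table`` is indexed by gene and carries ``fc1, fc2`` (RNA:
    wild-type and overexpressor 24h/0h) and ``fc3, fc4`` (protein
    counterparts); extra columns (gene_name, description, ...) are
    carried through.  Deltas are computed unrounded; pass flags use a
    strict |delta| > threshold rule and an undefined delta never passes.
    """
    deltas_rna = [differential_response(r.fc1, r.fc2) for r in fc_table.itertuples()]
    deltas_prot = [differential_response(r.fc3, r.fc4) for r in fc_table.itertuples()]
    out = fc_table.copy()
    out["delta_rna"] = deltas_rna
    out["delta_prot"] = deltas_prot
    dr = out["delta_rna"].to_numpy(float)
    dp = out["delta_prot"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        out["pass_rna"] = np.abs(dr) > threshold
        out["pass_prot"] = np.abs(dp) > threshold
    out["pass_rna"] &= np.isfinite(dr)
    out["pass_prot"] &= np.isfinite(dp)
    out["pass_any"] = out["pass_rna"] | out["pass_prot"]
    return out


def screen_genes(records: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Subset of screen records with |delta| > threshold at either level.

    Recomputes the pass flags at ``threshold`` from the stored deltas,
    so a table built at one threshold can be re-screened at another.
    Output rows are ordered by gene ID.
    """
    if records.empty:
        return records.copy()
    dr = records["delta_rna"].to_numpy(float)
    dp = records["delta_prot"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        keep = (np.isfinite(dr) & (np.abs(dr) > threshold)) | \
               (np.isfinite(dp) & (np.abs(dp) > threshold))
    return records[keep].sort_index()


def _fc_series(results: pd.DataFrame, genes: pd.Index,
               mapping: pd.Series | None = None) -> pd.Series:
    """Per-gene fold changes from a comparison result, via an optional
    gene->protein mapping."""
    if mapping is None:
        return results["fc"].reindex(genes)
    prot_ids = mapping.reindex(genes)
    fc = results["fc"].reindex(prot_ids)
    return pd.Series(fc.to_numpy(), index=genes)


def build_screen_report(rna_wt: pd.DataFrame, rna_ox: pd.DataFrame,
                        prot_wt: pd.DataFrame, prot_ox: pd.DataFrame,
                        association_wt: pd.DataFrame,
                        association_ox: pd.DataFrame,
                        gene2protein: pd.DataFrame,
                        gene_metadata: pd.DataFrame | None = None,
                        pool: str = "quadrant37",
                        threshold: float = 1.0) -> pd.DataFrame:
    """Assemble the full screen table from the four pipeline contrasts.

    The candidate pool is either the union of doubly-significant
    quadrant-3/7 genes from the two comparisons (``pool="quadrant37"``,
    the default) or every gene with an RNA measurement (``pool="all"``).
    One record per candidate; the ``pass_*`` flags mark the screen hits.
    """
    if not rna_wt.index.equals(rna_ox.index):
        raise ValueError("RNA contrasts cover different gene universes")
    if not prot_wt.index.equals(prot_ox.index):
        raise ValueError("protein contrasts cover different protein universes")
    if pool == "quadrant37":
        candidates = (concordant_significant_genes(association_wt)
                      | concordant_significant_genes(association_ox))
    elif pool == "all":
        candidates = set(rna_wt.index)
    else:
        raise ValueError(f"unknown pool mode {pool!r}")
    genes = pd.Index(sorted(candidates), name="gene")
    mapping = gene2protein.drop_duplicates().set_index("gene")["protein"]
    table = pd.DataFrame({
        "fc1": _fc_series(rna_wt, genes),
        "fc2": _fc_series(rna_ox, genes),
        "fc3": _fc_series(prot_wt, genes, mapping),
        "fc4": _fc_series(prot_ox, genes, mapping),
    }, index=genes)
    if gene_metadata is not None:
        table = table.join(gene_metadata, how="left")
    return build_screen_table(table, threshold=threshold)
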