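"""Differential protein abundance and proteome-level summaries.

Proteins quantified by data-independent acquisition are compared with a
two-sample t-test on log2 intensities (Student's equal-variance test by
default, Welch optional) and filtered at |fold change| > 1.5 with
BH-adjusted q < 0.05.  The q-value here is the Benjamini-Hochberg
adjusted p; no separate q-value estimator is used.  Fold changes are
ratios of linear-scale group means, and "down" means FC < 1/1.5 — the
threshold is symmetric on the log scale.

Also here: peptide-support and annotation-coverage summaries of the
identified proteome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Contrast, SampleSheet
from .rna import STATUS_DOWN, STATUS_NS, STATUS_UP, bh_adjust, _group_columns


def de_test_protein(intensities: pd.DataFrame, samples: SampleSheet,
                    contrast: Contrast, fc_threshold: float = 1.5,
                    q_threshold: float = 0.05,
                    equal_var: bool = True) -> pd.DataFrame:
    """Call differentially expressed proteins for one contrast.

    Intensities may contain missing values; a protein is testable when
    both groups retain at least two quantified replicates.  Proteins
    missing an entire group are flagged ``quantified=False``, excluded
    from testing and multiple-testing adjustment, and reported with
    NaN statistics.
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1 (linear scale)")
    treat, ctrl = _group_columns(samples, contrast)
    b = intensities[treat].to_numpy(float)
    a = intensities[ctrl].to_numpy(float)
    if np.nanmin(np.concatenate([b[~np.isnan(b)], a[~np.isnan(a)]])) <= 0:
        raise ValueError("protein intensities must be positive where present")

    quantified = (np.sum(~np.isnan(b), axis=1) >= 2) & (np.sum(~np.isnan(a), axis=1) >= 2)
    mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
    mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)

    fc = np.full(len(intensities), np.nan)
    fc[quantified] = mean_b[quantified] / mean_a[quantified]
    log2fc = np.log2(fc)

    p = np.full(len(intensities), np.nan)
    if quantified.any():
        res = stats.ttest_ind(np.log2(b[quantified]), np.log2(a[quantified]),
                              axis=1, equal_var=equal_var, nan_policy="omit")
        p_q = np.asarray(res.pvalue, dtype=float)
        p[quantified] = np.where(np.isnan(p_q), 1.0, p_q)

    q = np.full(len(intensities), np.nan)
    if quantified.any():
        q[quantified] = bh_adjust(p[quantified])

    status = np.full(len(intensities), STATUS_NS, dtype=object)
    up = quantified & (fc > fc_threshold) & (q < q_threshold)
    down = quantified & (fc < 1.0 / fc_threshold) & (q < q_threshold)
    status[up] = STATUS_UP
    status[down] = STATUS_DOWN

    return pd.DataFrame({"fc": fc, "log2fc": log2fc, "p": p, "fdr": q,
                         "status": status, "quantified": quantified},
                        index=intensities.index)


@dataclass(frozen=True)
class ProteomeSummary:
    """Identification-level summary of a DIA proteome."""

    n_peptides: int
    n_proteins: int
    n_multi_peptide: int
    pct_multi_peptide: float
    n_annotated: int | None = None
    pct_annotated: float | None = None


def summarize_peptide_support(peptide2protein: pd.DataFrame) -> ProteomeSummary:
    """Count peptides, proteins, and multi-peptide proteins.

    ``peptide2protein`` holds (peptide, protein) rows; duplicated rows
    and row order do not affect the result.  The multi-peptide
    percentage (proteins supported by more than one distinct peptide)
    is rounded to two decimals.
    """
    if peptide2protein.empty:
        raise ValueError("peptide-to-protein mapping is empty")
    pairs = peptide2protein[["peptide", "protein"]].drop_duplicates()
    n_peptides = pairs["peptide"].nunique()
    per_protein = pairs.groupby("protein")["peptide"].nunique()
    n_proteins = len(per_protein)
    n_multi = int((per_protein > 1).sum())
    return ProteomeSummary(
        n_peptides=int(n_peptides), n_proteins=int(n_proteins),
        n_multi_peptide=n_multi,
        pct_multi_peptide=round(100.0 * n_multi / n_proteins, 2))


def annotation_coverage(flags: pd.DataFrame) -> tuple[int, float]:
    """Fraction of proteins annotated in at least one database.

    ``flags`` is a boolean frame indexed by protein ID with one column
    per database.  Returns (count, percentage rounded to 2 decimals).
    """
    if flags.empty:
        raise ValueError("annotation flag table is empty")
    if not all(flags.dtypes == bool):
        raise ValueError("annotation flags must be boolean")
    annotated = flags.any(axis=1)
    n = int(annotated.sum())
    return n, round(100.0 * n / len(flags), 2)
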