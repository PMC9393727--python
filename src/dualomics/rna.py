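"""Transcript quantification and differential expression calling.

Expression is reported as FPKM (fragments per kilobase of transcript
per million mapped fragments); testing, however, runs on counts per
million.  The differential test is a deliberately transparent engine:
Welch's t-test on log2(CPM + pseudocount) with Benjamini-Hochberg
adjustment, and a gene is called differentially expressed when
|log2 fold change| > 1 and FDR < 0.05 (strict inequalities).  Fold
changes are ratios of group-mean CPM after adding the pseudocount, so
zero-count genes still have defined fold changes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Contrast, SampleSheet

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         mapped_totals: pd.Series | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments.

    FPKM[g, s] = counts[g, s] * 1e9 / (length[g] * total[s]).  When
    ``mapped_totals`` is omitted, per-sample column sums are used.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if mapped_totals is None:
        mapped_totals = counts.sum(axis=0)
    else:
        mapped_totals = mapped_totals.reindex(counts.columns)
        if mapped_totals.isna().any():
            raise ValueError("mapped_totals missing for some samples")
    if (mapped_totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    scale = np.outer(1.0 / lengths.to_numpy(float), 1.0 / mapped_totals.to_numpy(float))
    return pd.DataFrame(counts.to_numpy(float) * 1e9 * scale,
                        index=counts.index, columns=counts.columns)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million, by per-sample library size."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e6 / totals


def replicate_correlation(matrix: pd.DataFrame, samples: SampleSheet,
                          threshold: float = 0.866) -> pd.DataFrame:
    """Pairwise Pearson correlation of replicates within each group.

    Returns one row per within-group sample pair with columns
    ``genotype, timepoint, sample_a, sample_b, r, defined, below_threshold``.
    A constant replicate column makes the correlation undefined; such
    pairs are reported with ``defined=False`` rather than NaN-propagated
    into group minima.  Use :func:`min_replicate_correlation` for the
    per-group minimum.
    """
    rows = []
    for (gt, tp), members in samples.groups().items():
        if len(members) < 2:
            raise ValueError(f"group ({gt}, {tp}) has fewer than 2 replicates")
        for a, b in itertools.combinations(members, 2):
            x = matrix[a].to_numpy(float)
            y = matrix[b].to_numpy(float)
            defined = x.std() > 0 and y.std() > 0
            r = float(stats.pearsonr(x, y).statistic) if defined else np.nan
            rows.append({"genotype": gt, "timepoint": tp, "sample_a": a,
                         "sample_b": b, "r": r, "defined": defined,
                         "below_threshold": bool(defined and r < threshold)})
    return pd.DataFrame(rows)


def min_replicate_correlation(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-group minimum pairwise correlation over defined pairs."""
    defined = pairs[pairs["defined"]]
    out = (defined.groupby(["genotype", "timepoint"])["r"].min()
           .rename("min_r").reset_index())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotonicity is enforced; output is in the input order and clipped
    to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(samples: SampleSheet, contrast: Contrast) -> tuple[list[str], list[str]]:
    treat = samples.group(*contrast.treatment)
    ctrl = samples.group(*contrast.control)
    if len(treat) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"contrast {contrast.name}: each group needs >= 2 samples "
            f"(got {len(treat)} vs {len(ctrl)})")
    return treat, ctrl


def de_test_rna(counts: pd.DataFrame, samples: SampleSheet, contrast: Contrast,
                pseudocount: float = 1.0, log2fc_threshold: float = 1.0,
                fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Call differentially expressed genes for one contrast.

    Counts are normalized to CPM; the p-value comes from Welch's t-test
    on log2(CPM + pseudocount); the fold change is the ratio of group
    mean CPM (plus pseudocount).  Status is ``up`` when
    log2FC > log2fc_threshold and FDR < fdr_threshold, ``down``
    symmetrically, else ``ns``.
    """
    treat, ctrl = _group_columns(samples, contrast)
    norm = cpm(counts)
    log_norm = np.log2(norm + pseudocount)
    b = log_norm[treat].to_numpy(float)
    a = log_norm[ctrl].to_numpy(float)
    t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    # Genes constant across both groups: t is 0/0; no evidence of change.
    p = np.where(np.isnan(p), 1.0, p)
    fc = (norm[treat].mean(axis=1) + pseudocount) / (norm[ctrl].mean(axis=1) + pseudocount)
    log2fc = np.log2(fc)
    fdr = bh_adjust(p)
    status = np.where((log2fc > log2fc_threshold) & (fdr < fdr_threshold), STATUS_UP,
                      np.where((log2fc < -log2fc_threshold) & (fdr < fdr_threshold),
                               STATUS_DOWN, STATUS_NS))
    return pd.DataFrame({"fc": fc, "log2fc": log2fc, "p": p, "fdr": fdr,
                         "status": status}, index=counts.index)


def significant_features(result: pd.DataFrame) -> set[str]:
    """Feature IDs called up or down in a comparison result table."""
    return set(result.index[result["status"] != STATUS_NS])
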