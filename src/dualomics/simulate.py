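"""Synthetic paired transcriptome/proteome experiments with known truth.

The generator emulates a 2 genotype (wild type vs overexpressor) x
2 timepoint (0h vs 24h of treatment) x n replicate design.  RNA counts
are negative-binomial around gene-level baselines scaled by the planted
24h log2 fold change of each genotype; protein intensities are
log-normal around protein baselines scaled the same way.  A subset of
genes carries a planted differential response — the 24h effect differs
between genotypes by more than 1 on the log2 scale (drawn to exceed the
screen threshold by at least 0.5, so recovery is not boundary
dominated) — and a subset of annotation terms is planted onto those
genes.  Everything is derived from one :class:`numpy.random.Generator`
seeded from ``SimConfig.seed``, so a fixed seed fixes every output.

The returned :class:`TruthTable` records, per gene, the planted log2
fold changes in both layers and genotypes, the implied DE flags,
quadrants, differential-response deltas and screen flag, giving every
downstream stage a recoverable answer key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .association import assign_quadrant
from .config import SampleSheet, SimConfig

#: Mix of planted protein behaviour for genes with a measured protein:
#: effects mirroring the RNA, no protein change, or an independent
#: protein-only effect in one genotype.
PROTEIN_MODES = ("concordant", "null", "independent")
PROTEIN_MODE_PROBS = (0.7, 0.15, 0.15)


@dataclass
class SimulatedDataset:
    """One synthetic experiment: matrices, mappings, annotation, truth."""

    rna: pd.DataFrame                 # genes x samples integer counts
    protein: pd.DataFrame             # proteins x samples intensities
    lengths: pd.Series                # per-gene transcript length (bp)
    gene2protein: pd.DataFrame        # columns gene, protein
    peptide2protein: pd.DataFrame     # columns peptide, protein
    annotation_flags: pd.DataFrame    # proteins x {go, kegg, kog} booleans
    terms: pd.DataFrame               # columns term, feature (gene IDs)
    term_truth: pd.DataFrame          # term -> planted flag
    samples: SampleSheet
    truth: pd.DataFrame               # per-gene planted ground truth


def _balanced_sign(rng: np.random.Generator, magnitude) -> np.ndarray:
    """Effect signs keeping the perturbed library mass unbiased.

    An up-probability of 1 / (2^|e| + 1) makes E[2^(s*e)] = 1, so the
    expected total expression mass of a treated library matches the
    untreated one and per-library (CPM-style) normalization stays
    unbiased for null genes.  A side effect matching real stress data:
    large effects are predominantly downregulation.
    """
    magnitude = np.atleast_1d(np.asarray(magnitude, dtype=float))
    p_up = 1.0 / (np.exp2(magnitude) + 1.0)
    return np.where(rng.random(magnitude.shape) < p_up, 1.0, -1.0)


def _planted_rna_effects(cfg: SimConfig, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene planted RNA log2 fold changes (24h vs 0h) per genotype."""
    n = cfg.n_genes
    lo, hi = cfg.planted_log2fc_range
    l2fc_wt = np.zeros(n)
    l2fc_ox = np.zeros(n)
    perm = rng.permutation(n)

    # Differential-response genes: |ox - wt| drawn in [1.5, 3].
    n_dr = round(cfg.frac_diff_response * n)
    for i, g in enumerate(perm[:n_dr]):
        mag = rng.uniform(1.5, 3.0)
        delta = _balanced_sign(rng, mag)[0] * mag
        if i % 2 == 0:  # responds in the overexpressor only
            l2fc_ox[g] = delta
        else:           # responds in both, by different amounts
            base_mag = rng.uniform(max(lo, 1e-6), hi)
            base = _balanced_sign(rng, base_mag)[0] * base_mag
            l2fc_wt[g] = base
            l2fc_ox[g] = base + delta

    # Shared responders: identical effect in both genotypes (delta 0).
    n_type_b = sum(1 for i in range(n_dr) if i % 2 == 1)
    n_shared = max(0, round(cfg.frac_de_wt * n) - n_type_b)
    shared = perm[n_dr:n_dr + n_shared]
    mag = rng.uniform(max(lo, 1e-6), hi, n_shared)
    eff = _balanced_sign(rng, mag) * mag
    l2fc_wt[shared] = eff
    l2fc_ox[shared] = eff

    # Overexpressor-only responders to reach frac_de_ox if it exceeds
    # what the blocks above supply (these also differ between genotypes).
    n_ox_so_far = n_dr + n_shared
    n_extra = max(0, round(cfg.frac_de_ox * n) - n_ox_so_far)
    extra = perm[n_dr + n_shared:n_dr + n_shared + n_extra]
    mag = rng.uniform(max(lo, 1e-6), hi, n_extra)
    l2fc_ox[extra] = _balanced_sign(rng, mag) * mag
    return l2fc_wt, l2fc_ox


def _planted_protein_effects(cfg: SimConfig, rng: np.random.Generator,
                             has_protein: np.ndarray,
                             rna_wt: np.ndarray, rna_ox: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    n = cfg.n_genes
    lo, hi = cfg.planted_log2fc_range
    prot_wt = np.zeros(n)
    prot_ox = np.zeros(n)
    p_plant = max(cfg.frac_de_wt, cfg.frac_de_ox)
    for g in np.flatnonzero(has_protein):
        mode = rng.choice(len(PROTEIN_MODES), p=PROTEIN_MODE_PROBS)
        if PROTEIN_MODES[mode] == "concordant":
            prot_wt[g] = rna_wt[g]
            prot_ox[g] = rna_ox[g]
        elif PROTEIN_MODES[mode] == "independent" and rng.random() < p_plant:
            eff = rng.choice([-1, 1]) * rng.uniform(max(lo, 1e-6), hi)
            if rng.random() < 0.5:
                prot_wt[g] = eff
            else:
                prot_ox[g] = eff
        # "null" (and unplanted "independent"): protein unchanged
    return prot_wt, prot_ox


def _truth_table(cfg: SimConfig, genes: list[str], has_protein: np.ndarray,
                 rna_wt, rna_ox, prot_wt, prot_ox) -> pd.DataFrame:
    quad_wt = np.full(cfg.n_genes, np.nan)
    quad_ox = np.full(cfg.n_genes, np.nan)
    prot_thr = math.log2(1.5)
    for g in np.flatnonzero(has_protein):
        quad_wt[g] = assign_quadrant(rna_wt[g], prot_wt[g], 1.0, prot_thr)
        quad_ox[g] = assign_quadrant(rna_ox[g], prot_ox[g], 1.0, prot_thr)
    delta_rna = rna_ox - rna_wt
    delta_prot = np.where(has_protein, prot_ox - prot_wt, np.nan)
    with np.errstate(invalid="ignore"):
        screen = (np.abs(delta_rna) > 1.0) | (has_protein & (np.abs(delta_prot) > 1.0))
    return pd.DataFrame({
        "has_protein": has_protein,
        "rna_log2fc_wt": rna_wt, "rna_log2fc_ox": rna_ox,
        "prot_log2fc_wt": np.where(has_protein, prot_wt, np.nan),
        "prot_log2fc_ox": np.where(has_protein, prot_ox, np.nan),
        "de_rna_wt": rna_wt != 0, "de_rna_ox": rna_ox != 0,
        "de_prot_wt": has_protein & (prot_wt != 0),
        "de_prot_ox": has_protein & (prot_ox != 0),
        "quadrant_wt": quad_wt, "quadrant_ox": quad_ox,
        "delta_rna": delta_rna, "delta_prot": delta_prot,
        "screen_flag": screen,
    }, index=pd.Index(genes, name="gene"))


def _simulate_terms(cfg: SimConfig, rng: np.random.Generator,
                    genes: list[str], screen_flag: np.ndarray
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    screen_genes = [g for g, f in zip(genes, screen_flag) if f]
    other_genes = [g for g, f in zip(genes, screen_flag) if not f]
    n_planted = round(cfg.frac_enriched_terms * cfg.n_terms)
    rows, truth_rows = [], []
    for t in range(cfg.n_terms):
        term = f"T{t + 1:03d}"
        size = int(rng.integers(10, 26))
        planted = t < n_planted and len(screen_genes) >= 3
        if planted:
            n_hit = min(len(screen_genes), max(3, int(round(0.7 * size))))
            members = list(rng.choice(screen_genes, n_hit, replace=False))
            n_rest = min(len(other_genes), size - n_hit)
            if n_rest > 0:
                members += list(rng.choice(other_genes, n_rest, replace=False))
        else:
            members = list(rng.choice(genes, min(size, len(genes)), replace=False))
        rows.extend({"term": term, "feature": m} for m in sorted(members))
        truth_rows.append({"term": term, "planted": planted})
    terms = pd.DataFrame(rows, columns=["term", "feature"])
    term_truth = pd.DataFrame(truth_rows, columns=["term", "planted"]).set_index("term")
    return terms, term_truth


def simulate_experiment(config: SimConfig) -> SimulatedDataset:
    """Generate one paired RNA/protein dataset with its answer key."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i + 1:05d}" for i in range(n)]
    samples = SampleSheet.design(config.replicates)

    rna_wt, rna_ox = _planted_rna_effects(config, rng)
    n_prot = round(config.protein_fraction * n)
    prot_idx = np.sort(rng.choice(n, n_prot, replace=False))
    has_protein = np.zeros(n, dtype=bool)
    has_protein[prot_idx] = True
    prot_wt, prot_ox = _planted_protein_effects(config, rng, has_protein,
                                                rna_wt, rna_ox)

    lengths = pd.Series(rng.integers(config.gene_length_range[0],
                                     config.gene_length_range[1] + 1, n),
                        index=pd.Index(genes, name="gene"), name="length")

    # RNA counts: negative binomial, mean = relative abundance x library
    # size x 2^(planted effect at 24h).
    weights = rng.lognormal(0.0, 1.0, n)
    rel = weights / weights.sum()
    effect = {"WT": rna_wt, "OX": rna_ox}
    counts = {}
    r = 1.0 / config.nb_dispersion
    for _, row in samples.frame.iterrows():
        lib = config.mean_depth * rng.uniform(0.85, 1.15)
        mu = rel * lib
        if row["timepoint"] == "24h":
            mu = mu * np.exp2(effect[row["genotype"]])
        counts[row["sample"]] = rng.negative_binomial(r, r / (r + mu))
    rna = pd.DataFrame(counts, index=pd.Index(genes, name="gene"))

    # Protein intensities: log-normal noise with the configured CV.
    proteins = [f"P{i + 1:05d}" for i in prot_idx]
    gene2protein = pd.DataFrame({"gene": [genes[i] for i in prot_idx],
                                 "protein": proteins})
    base = rng.lognormal(math.log(1e5), 1.0, n_prot)
    sigma = math.sqrt(math.log(1.0 + config.protein_cv ** 2))
    p_effect = {"WT": prot_wt[prot_idx], "OX": prot_ox[prot_idx]}
    intens = {}
    for _, row in samples.frame.iterrows():
        mu = base.copy()
        if row["timepoint"] == "24h":
            mu = mu * np.exp2(p_effect[row["genotype"]])
        intens[row["sample"]] = mu * rng.lognormal(0.0, sigma, n_prot)
    protein = pd.DataFrame(intens, index=pd.Index(proteins, name="protein"))

    # Peptide support (1 + Poisson) and database annotation flags.
    n_pep = 1 + rng.poisson(2.5, n_prot)
    pep_rows = []
    pep_counter = 0
    for prot, k in zip(proteins, n_pep):
        for _ in range(int(k)):
            pep_counter += 1
            pep_rows.append({"peptide": f"PEP{pep_counter:06d}", "protein": prot})
    peptide2protein = pd.DataFrame(pep_rows)
    annotation_flags = pd.DataFrame({
        "go": rng.random(n_prot) < 0.85,
        "kegg": rng.random(n_prot) < 0.60,
        "kog": rng.random(n_prot) < 0.50,
    }, index=pd.Index(proteins, name="protein"))

    truth = _truth_table(config, genes, has_protein, rna_wt, rna_ox,
                         prot_wt, prot_ox)
    terms, term_truth = _simulate_terms(config, rng, genes,
                                        truth["screen_flag"].to_numpy())
    return SimulatedDataset(rna=rna, protein=protein, lengths=lengths,
                            gene2protein=gene2protein,
                            peptide2protein=peptide2protein,
                            annotation_flags=annotation_flags,
                            terms=terms, term_truth=term_truth,
                            samples=samples, truth=truth)


#: File names used by write_dataset / read_dataset.
DATASET_FILES = {
    "rna": "counts.tsv", "protein": "protein.tsv", "lengths": "lengths.tsv",
    "gene2protein": "gene2protein.tsv", "peptide2protein": "peptide2protein.tsv",
    "annotation_flags": "annotation_flags.tsv", "terms": "terms.tsv",
    "term_truth": "term_truth.tsv", "samples": "samples.tsv", "truth": "truth.tsv",
}


def write_dataset(dataset: SimulatedDataset, directory) -> dict[str, Path]:
    """Write every component of a dataset as TSV; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = {k: directory / v for k, v in DATASET_FILES.items()}
    dio.write_table(dataset.rna, f["rna"])
    dio.write_table(dataset.protein, f["protein"])
    dio.write_table(dataset.lengths, f["lengths"])
    dio.write_table(dataset.gene2protein, f["gene2protein"], index=False)
    dio.write_table(dataset.peptide2protein, f["peptide2protein"], index=False)
    dio.write_table(dataset.annotation_flags, f["annotation_flags"])
    dio.write_table(dataset.terms, f["terms"], index=False)
    dio.write_table(dataset.term_truth, f["term_truth"])
    dio.write_table(dataset.samples.frame, f["samples"], index=False)
    dio.write_table(dataset.truth, f["truth"])
    return f


def read_dataset(directory) -> SimulatedDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    f = {k: directory / v for k, v in DATASET_FILES.items()}
    rna = dio.read_matrix(f["rna"]).astype(int)
    protein = dio.read_matrix(f["protein"])
    lengths = dio.read_series(f["lengths"], "length")
    truth = dio._read_tsv(f["truth"]).set_index("gene")
    for col in ("has_protein", "de_rna_wt", "de_rna_ox", "de_prot_wt",
                "de_prot_ox", "screen_flag"):
        truth[col] = truth[col].astype(bool)
    flags = dio._read_tsv(f["annotation_flags"]).set_index("protein").astype(bool)
    term_truth = dio._read_tsv(f["term_truth"]).set_index("term")
    term_truth["planted"] = term_truth["planted"].astype(bool)
    return SimulatedDataset(
        rna=rna, protein=protein, lengths=lengths,
        gene2protein=dio.read_gene2protein(f["gene2protein"]),
        peptide2protein=dio.read_peptide2protein(f["peptide2protein"]),
        annotation_flags=flags,
        terms=dio.read_annotation(f["terms"]),
        term_truth=term_truth,
        samples=dio.read_sample_sheet(f["samples"]),
        truth=truth)
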