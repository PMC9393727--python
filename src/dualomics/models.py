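"""Model/results surface tying the pipeline stages together.

:class:`DualOmicsExperiment` holds the data of one paired
transcriptome/proteome experiment (count matrix, intensity matrix,
sample sheet, gene-protein mapping, optional lengths, peptide support,
database flags and term annotation).  Calling :meth:`fit` runs every
stage — quantification, replicate QC, per-contrast differential
expression in both layers, Venn accounting, nine-quadrant association,
the cross-genotype differential-response screen and term enrichment —
and returns a :class:`DualOmicsResults` carrying all stage tables, with
a ``summary()`` and a ``save()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import association as assoc
from . import enrichment as enr
from . import io as dio
from . import protein as prot_mod
from . import rna as rna_mod
from . import screen as screen_mod
from . import simulate as sim_mod
from .config import (ALL_CONTRASTS, OX_RESPONSE, WT_RESPONSE, PipelineConfig,
                     SampleSheet, SimConfig)


class DualOmicsExperiment:
    """A paired RNA/protein experiment ready to be fitted."""

    def __init__(self, rna_counts: pd.DataFrame, protein: pd.DataFrame,
                 samples: SampleSheet, gene2protein: pd.DataFrame,
                 lengths: pd.Series | None = None,
                 peptide2protein: pd.DataFrame | None = None,
                 annotation_flags: pd.DataFrame | None = None,
                 terms: pd.DataFrame | None = None,
                 gene_metadata: pd.DataFrame | None = None):
        missing = [s for s in samples.samples if s not in rna_counts.columns]
        if missing:
            raise ValueError(f"samples absent from the RNA matrix: {missing}")
        missing_p = [s for s in samples.samples if s not in protein.columns]
        if missing_p:
            raise ValueError(f"samples absent from the protein matrix: {missing_p}")
        self.rna_counts = rna_counts
        self.protein = protein
        self.samples = samples
        self.gene2protein = gene2protein
        self.lengths = lengths
        self.peptide2protein = peptide2protein
        self.annotation_flags = annotation_flags
        self.terms = terms
        self.gene_metadata = gene_metadata

    @classmethod
    def from_dataset(cls, ds: sim_mod.SimulatedDataset) -> "DualOmicsExperiment":
        return cls(ds.rna, ds.protein, ds.samples, ds.gene2protein,
                   lengths=ds.lengths, peptide2protein=ds.peptide2protein,
                   annotation_flags=ds.annotation_flags, terms=ds.terms)

    @classmethod
    def from_directory(cls, directory) -> "DualOmicsExperiment":
        """Build from a directory of TSVs as written by the simulator."""
        return cls.from_dataset(sim_mod.read_dataset(directory))

    @classmethod
    def simulate(cls, sim_config: SimConfig
                 ) -> tuple["DualOmicsExperiment", sim_mod.SimulatedDataset]:
        """Simulate an experiment; also returns the full dataset (truth)."""
        ds = sim_mod.simulate_experiment(sim_config)
        return cls.from_dataset(ds), ds

    def fit(self, config: PipelineConfig | None = None) -> "DualOmicsResults":
        config = config or PipelineConfig()
        config.validate()

        fpkm = None
        if self.lengths is not None:
            fpkm = rna_mod.fpkm(self.rna_counts, self.lengths)
        log_expr = np.log2(rna_mod.cpm(self.rna_counts) + config.pseudocount)
        correlations = rna_mod.replicate_correlation(
            log_expr, self.samples, threshold=config.correlation_threshold)

        rna_de = {c.name: rna_mod.de_test_rna(
            self.rna_counts, self.samples, c, pseudocount=config.pseudocount,
            log2fc_threshold=config.rna_log2fc, fdr_threshold=config.rna_fdr)
            for c in ALL_CONTRASTS}
        protein_de = {c.name: prot_mod.de_test_protein(
            self.protein, self.samples, c, fc_threshold=config.protein_fc,
            q_threshold=config.protein_q,
            equal_var=(config.protein_test == "student"))
            for c in (WT_RESPONSE, OX_RESPONSE)}

        venn_deg = assoc.venn_overlap(
            rna_mod.significant_features(rna_de[WT_RESPONSE.name]),
            rna_mod.significant_features(rna_de[OX_RESPONSE.name]))
        venn_dep = assoc.venn_overlap(
            rna_mod.significant_features(protein_de[WT_RESPONSE.name]),
            rna_mod.significant_features(protein_de[OX_RESPONSE.name]))

        association = {}
        quadrants = {}
        for c in (WT_RESPONSE, OX_RESPONSE):
            table = assoc.associate(rna_de[c.name], protein_de[c.name],
                                    self.gene2protein,
                                    rna_thr=config.rna_log2fc,
                                    prot_thr=config.protein_log2fc)
            association[c.name] = table
            quadrants[c.name] = assoc.quadrant_counts(table)

        screen = screen_mod.build_screen_report(
            rna_de[WT_RESPONSE.name], rna_de[OX_RESPONSE.name],
            protein_de[WT_RESPONSE.name], protein_de[OX_RESPONSE.name],
            association[WT_RESPONSE.name], association[OX_RESPONSE.name],
            self.gene2protein, gene_metadata=self.gene_metadata,
            pool=config.screen_pool, threshold=config.delta_threshold)
        screen_hits = screen_mod.screen_genes(screen, config.delta_threshold)

        proteome_summary = None
        if self.peptide2protein is not None and len(self.peptide2protein):
            proteome_summary = prot_mod.summarize_peptide_support(self.peptide2protein)
            if self.annotation_flags is not None and len(self.annotation_flags):
                n_ann, pct_ann = prot_mod.annotation_coverage(self.annotation_flags)
                proteome_summary = prot_mod.ProteomeSummary(
                    n_peptides=proteome_summary.n_peptides,
                    n_proteins=proteome_summary.n_proteins,
                    n_multi_peptide=proteome_summary.n_multi_peptide,
                    pct_multi_peptide=proteome_summary.pct_multi_peptide,
                    n_annotated=n_ann, pct_annotated=pct_ann)

        enrichment = {}
        if self.terms is not None and len(self.terms):
            background = list(self.rna_counts.index)
            hits = [g for g in screen_hits.index if g in set(background)]
            if hits:
                direction = {}
                for g in hits:
                    d = screen_hits.loc[g, "delta_rna"]
                    if not np.isfinite(d):
                        d = screen_hits.loc[g, "delta_prot"]
                    direction[g] = "up" if d > 0 else "down"
                enrichment["screen"] = enr.enrich(
                    hits, background, self.terms, direction=direction,
                    alpha=config.enrichment_alpha)
            for c in (WT_RESPONSE, OX_RESPONSE):
                res = rna_de[c.name]
                degs = res.index[res["status"] != rna_mod.STATUS_NS]
                if len(degs):
                    enrichment[f"deg_{c.name}"] = enr.enrich(
                        degs, background, self.terms,
                        direction=res.loc[degs, "status"],
                        alpha=config.enrichment_alpha)

        return DualOmicsResults(
            model=self, config=config, fpkm=fpkm, correlations=correlations,
            rna_de=rna_de, protein_de=protein_de, venn_deg=venn_deg,
            venn_dep=venn_dep, association=association,
            quadrant_counts=quadrants, screen=screen, screen_hits=screen_hits,
            proteome_summary=proteome_summary, enrichment=enrichment)


@dataclass
class DualOmicsResults:
    """Everything one fit produced, stage by stage."""

    model: DualOmicsExperiment
    config: PipelineConfig
    fpkm: pd.DataFrame | None
    correlations: pd.DataFrame
    rna_de: dict[str, pd.DataFrame]
    protein_de: dict[str, pd.DataFrame]
    venn_deg: assoc.VennSummary
    venn_dep: assoc.VennSummary
    association: dict[str, pd.DataFrame]
    quadrant_counts: dict[str, pd.DataFrame]
    screen: pd.DataFrame
    screen_hits: pd.DataFrame
    proteome_summary: prot_mod.ProteomeSummary | None
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)

    def deg_sets(self) -> dict[str, set[str]]:
        return {name: rna_mod.significant_features(res)
                for name, res in self.rna_de.items()}

    def dep_sets(self) -> dict[str, set[str]]:
        return {name: rna_mod.significant_features(res)
                for name, res in self.protein_de.items()}

    def summary(self) -> str:
        """Human-readable run report."""
        lines = ["Dual-omics differential response analysis",
                 "=" * 45,
                 f"genes: {len(self.model.rna_counts)}   "
                 f"proteins: {len(self.model.protein)}   "
                 f"samples: {len(self.model.samples)}"]
        min_r = rna_mod.min_replicate_correlation(self.correlations)
        if len(min_r):
            lines.append(f"replicate correlation (min over groups): "
                         f"{min_r['min_r'].min():.3f} "
                         f"(threshold {self.config.correlation_threshold})")
        lines.append("")
        lines.append("differentially expressed genes "
                     f"(|log2FC| > {self.config.rna_log2fc}, FDR < {self.config.rna_fdr}):")
        for name, s in self.deg_sets().items():
            lines.append(f"  {name}: {len(s)}")
        lines.append("differentially expressed proteins "
                     f"(|FC| > {self.config.protein_fc}, q < {self.config.protein_q}):")
        for name, s in self.dep_sets().items():
            lines.append(f"  {name}: {len(s)}")
        lines.append(f"DEG overlap between responses: {self.venn_deg.n_common} "
                     f"({self.venn_deg.pct_shared:.2f}%)")
        lines.append(f"DEP overlap between responses: {self.venn_dep.n_common} "
                     f"({self.venn_dep.pct_shared:.2f}%)")
        for name, counts in self.quadrant_counts.items():
            q3, q7 = counts.loc[3], counts.loc[7]
            lines.append(f"quadrants ({name}): "
                         f"Q3 {q3['total']} ({q3['significant']} significant), "
                         f"Q7 {q7['total']} ({q7['significant']} significant)")
        lines.append(f"differential-response screen "
                     f"(|Delta| > {self.config.delta_threshold}, pool={self.config.screen_pool}): "
                     f"{len(self.screen_hits)} of {len(self.screen)} candidates")
        if self.proteome_summary is not None:
            ps = self.proteome_summary
            lines.append(f"proteome: {ps.n_peptides} peptides, {ps.n_proteins} proteins, "
                         f"{ps.n_multi_peptide} ({ps.pct_multi_peptide:.2f}%) multi-peptide")
            if ps.pct_annotated is not None:
                lines.append(f"  annotated in >=1 database: {ps.n_annotated} "
                             f"({ps.pct_annotated:.2f}%)")
        for name, table in self.enrichment.items():
            n_sig = int(table["significant"].sum())
            lines.append(f"enrichment ({name}): {n_sig} significant of {len(table)} terms")
        return "\n".join(lines)

    def save(self, directory) -> dict[str, Path]:
        """Write every stage artifact as TSV plus the text summary."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        prov = {"generator": f"dualomics {__version__}",
                "config_hash": self.config.config_hash()}
        paths: dict[str, Path] = {}

        def put(name: str, obj, **kw):
            paths[name] = dio.write_table(obj, directory / f"{name}.tsv",
                                          provenance=prov, **kw)

        if self.fpkm is not None:
            put("fpkm", self.fpkm)
        put("replicate_correlation", self.correlations, index=False)
        for name, res in self.rna_de.items():
            put(f"de_rna_{name}", res)
        for name, res in self.protein_de.items():
            put(f"de_protein_{name}", res)
        venn = pd.DataFrame([
            {"comparison": "DEG", **self.venn_deg.__dict__},
            {"comparison": "DEP", **self.venn_dep.__dict__}])
        put("venn", venn, index=False)
        for name, table in self.association.items():
            put(f"association_{name}", table)
            put(f"quadrant_counts_{name}", self.quadrant_counts[name])
        put("screen", self.screen)
        put("screen_hits", self.screen_hits)
        for name, table in self.enrichment.items():
            put(f"enrichment_{name}", table)
        if self.proteome_summary is not None:
            put("proteome_summary",
                pd.DataFrame([self.proteome_summary.__dict__]), index=False)
        self.config.to_yaml(directory / "config.yaml")
        summary_path = directory / "summary.txt"
        summary_path.write_text(self.summary() + "\n", encoding="utf-8")
        paths["summary"] = summary_path
        return paths
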