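"""Configuration objects for simulation and for the analysis pipeline.

Two dataclasses live here: :class:`SimConfig`, which parameterizes the
paired RNA/protein experiment simulator, and :class:`PipelineConfig`,
which carries every decision threshold used downstream.  The pipeline
defaults encode the published filtering rules for this kind of study:
DEGs at |log2FC| > 1 with BH FDR < 0.05, DEPs at |FC| > 1.5 with
q < 0.05, the differential-response screen at |Delta| > 1, a replicate
correlation floor of 0.866 and top-20 term reporting.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

GENOTYPES = ("WT", "OX")
TIMEPOINTS = ("0h", "24h")


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: *treatment* vs *control*.

    Each side is a ``(genotype, timepoint)`` pair.  Fold changes are
    always treatment / control.
    """

    name: str
    treatment: tuple[str, str]
    control: tuple[str, str]

    def flipped(self) -> "Contrast":
        return Contrast(f"{self.name}_flipped", self.control, self.treatment)


#: The four comparisons of the 2 genotype x 2 timepoint design.
WT_RESPONSE = Contrast("WT24h_vs_WT0h", ("WT", "24h"), ("WT", "0h"))
OX_RESPONSE = Contrast("OX24h_vs_OX0h", ("OX", "24h"), ("OX", "0h"))
BASELINE = Contrast("OX0h_vs_WT0h", ("OX", "0h"), ("WT", "0h"))
TREATED = Contrast("OX24h_vs_WT24h", ("OX", "24h"), ("WT", "24h"))
ALL_CONTRASTS = (WT_RESPONSE, OX_RESPONSE, BASELINE, TREATED)


class SampleSheet:
    """Maps sample IDs to (genotype, timepoint, replicate).

    Wraps a DataFrame with columns ``sample, genotype, timepoint,
    replicate``; ``sample`` must be unique.
    """

    REQUIRED = ("sample", "genotype", "timepoint", "replicate")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        frame = frame.copy()
        frame["sample"] = frame["sample"].astype(str)
        if frame["sample"].duplicated().any():
            dups = frame.loc[frame["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        bad_gt = set(frame["genotype"]) - set(GENOTYPES)
        if bad_gt:
            raise ValueError(f"unknown genotypes {sorted(bad_gt)}; expected {GENOTYPES}")
        bad_tp = set(frame["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def samples(self) -> list[str]:
        return self.frame["sample"].tolist()

    def group(self, genotype: str, timepoint: str) -> list[str]:
        """Sample IDs belonging to one (genotype, timepoint) cell."""
        m = (self.frame["genotype"] == genotype) & (self.frame["timepoint"] == timepoint)
        return self.frame.loc[m, "sample"].tolist()

    def groups(self) -> dict[tuple[str, str], list[str]]:
        out: dict[tuple[str, str], list[str]] = {}
        for (gt, tp), sub in self.frame.groupby(["genotype", "timepoint"], sort=True):
            out[(gt, tp)] = sub["sample"].tolist()
        return out

    @classmethod
    def design(cls, replicates: int = 3) -> "SampleSheet":
        """The standard 2 genotype x 2 timepoint x n replicate layout."""
        rows = []
        for gt in GENOTYPES:
            for tp in TIMEPOINTS:
                for r in range(1, replicates + 1):
                    rows.append({"sample": f"{gt}_{tp}_r{r}", "genotype": gt,
                                 "timepoint": tp, "replicate": r})
        return cls(pd.DataFrame(rows))


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic paired-omics experiment.

    Defaults emulate a root salt-stress time course in a transgenic vs
    wild-type grass: 2 genotypes x 2 timepoints x 3 replicates, ~1M
    mapped fragments per RNA library, negative-binomial counts, and
    log-normal protein intensities for a 60% subset of genes.
    """

    n_genes: int = 2000
    protein_fraction: float = 0.6
    replicates: int = 3
    nb_dispersion: float = 0.1
    protein_cv: float = 0.2
    frac_de_wt: float = 0.2
    frac_de_ox: float = 0.2
    planted_log2fc_range: tuple[float, float] = (1.5, 4.0)
    frac_diff_response: float = 0.05
    n_terms: int = 50
    frac_enriched_terms: float = 0.2
    mean_depth: float = 1.0e6
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.replicates < 2:
            raise ValueError(
                "replicates must be >= 2 (two-group tests are undefined "
                f"with a single replicate), got {self.replicates}")
        if self.nb_dispersion <= 0 or self.protein_cv <= 0:
            raise ValueError("nb_dispersion and protein_cv must be positive")
        if not (0.0 < self.protein_fraction <= 1.0):
            raise ValueError(f"protein_fraction must lie in (0, 1], got {self.protein_fraction}")
        for name in ("frac_de_wt", "frac_de_ox", "frac_diff_response", "frac_enriched_terms"):
            _check_fraction(name, getattr(self, name))
        lo, hi = self.planted_log2fc_range
        if lo < 0 or hi < lo:
            raise ValueError(f"planted_log2fc_range must be 0 <= lo <= hi, got {self.planted_log2fc_range}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.n_terms < 0:
            raise ValueError("n_terms must be non-negative")


@dataclass
class PipelineConfig:
    """All decision thresholds and engine options of the pipeline.

    The defaults reproduce the published filters exactly:
    rna_log2fc=1, rna_fdr=0.05, protein_fc=1.5, protein_q=0.05,
    delta_threshold=1, correlation_threshold=0.866, top_n=20.
    All threshold comparisons are strict (values landing exactly on a
    boundary fall to the non-significant side).
    """

    rna_log2fc: float = 1.0
    rna_fdr: float = 0.05
    protein_fc: float = 1.5
    protein_q: float = 0.05
    delta_threshold: float = 1.0
    correlation_threshold: float = 0.866
    top_n: int = 20
    pseudocount: float = 1.0
    protein_test: str = "student"  # "student" (equal variance) or "welch"
    screen_pool: str = "quadrant37"  # or "all"
    enrichment_alpha: float = 0.05
    seed: int = 0

    @property
    def protein_log2fc(self) -> float:
        """The DEP fold-change threshold on the log2 scale."""
        return math.log2(self.protein_fc)

    def validate(self) -> None:
        if self.protein_test not in ("student", "welch"):
            raise ValueError(f"protein_test must be 'student' or 'welch', got {self.protein_test!r}")
        if self.screen_pool not in ("quadrant37", "all"):
            raise ValueError(f"screen_pool must be 'quadrant37' or 'all', got {self.screen_pool!r}")
        if self.protein_fc <= 0:
            raise ValueError("protein_fc must be positive")
        for name in ("rna_fdr", "protein_q", "enrichment_alpha"):
            _check_fraction(name, getattr(self, name))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for provenance lines."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
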