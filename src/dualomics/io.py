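"""Readers and writers for the pipeline's tab-separated artifacts.

All tables are UTF-8 TSV with a header row; matrices carry the feature
ID in the first column.  Writers may prepend provenance comment lines
starting with ``#``, which every reader here skips.  The published
36-gene fold-change table ships with the package and is loaded with
:func:`load_table1`; its missing cells are printed as a backslash and
its minus signs as U+2212, both normalized on ingest.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SampleSheet

#: Values treated as missing in ingested tables (the backslash is how
#: the published table prints cells without evidence).
NA_VALUES = ["\\", "", "NA", "NaN", "nan"]


def _count_header_comments(path: Path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    skip = _count_header_comments(path)
    return pd.read_csv(path, sep="\t", skiprows=skip, na_values=NA_VALUES,
                       keep_default_na=False, **kwargs)


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples numeric matrix.

    First column is the feature ID.  Duplicate feature IDs and
    non-numeric cells are rejected with the offending ID / line number.
    """
    path = Path(path)
    df = _read_tsv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: matrix needs a feature column and at least one sample column")
    feature_col = df.columns[0]
    df = df.set_index(feature_col)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature IDs: {dup[:5]}")
    header_lines = _count_header_comments(path) + 1
    numeric = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, line {header_lines + row + 1}")
        numeric[col] = converted
    out = pd.DataFrame(numeric, index=df.index)
    out.index.name = feature_col
    return out


def write_table(obj: pd.DataFrame | pd.Series, path, *, index: bool = True,
                provenance: dict | None = None) -> Path:
    """Write a table as TSV, optionally with ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame = obj.to_frame() if isinstance(obj, pd.Series) else obj
        frame.to_csv(fh, sep="\t", index=index)
    return path


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(_read_tsv(path))


def read_mapping(path, left: str, right: str) -> pd.DataFrame:
    """Read a two-column mapping table, checking the expected header."""
    df = _read_tsv(path, dtype=str)
    for col in (left, right):
        if col not in df.columns:
            raise ValueError(f"{path}: expected a {col!r} column, found {list(df.columns)}")
    return df[[left, right]]


def read_gene2protein(path) -> pd.DataFrame:
    return read_mapping(path, "gene", "protein")


def read_peptide2protein(path) -> pd.DataFrame:
    return read_mapping(path, "peptide", "protein")


def read_series(path, name: str) -> pd.Series:
    """Read a two-column (feature, value) TSV as a numeric Series."""
    df = _read_tsv(path)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns, found {df.shape[1]}")
    s = df.set_index(df.columns[0])[df.columns[1]]
    return pd.to_numeric(s).rename(name)


def read_annotation(path) -> pd.DataFrame:
    """Read a term annotation as (term, feature) pairs.

    Accepts either a two-column TSV with a ``term``/``feature`` header
    or GMT (term <tab> description <tab> member...).
    """
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                rows.extend({"term": parts[0], "feature": m} for m in parts[2:] if m)
        return pd.DataFrame(rows, columns=["term", "feature"])
    return read_mapping(path, "term", "feature")


_UNICODE_MINUS = "−"


def load_table1(path=None) -> pd.DataFrame:
    """Load the packaged 36-gene fold-change table.

    Columns: gene_id, fc1/fc2 (RNA fold changes, WT and overexpressor
    24h/0h), the printed log2(FC2/FC1), fc3/fc4 (the protein
    counterparts), the printed log2(FC4/FC3), gene_name, description.
    Backslash cells become NaN; U+2212 minus signs become ASCII.
    """
    if path is None:
        ref = importlib.resources.files("dualomics").joinpath("data/table1.tsv")
        with importlib.resources.as_file(ref) as p:
            return load_table1(p)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=NA_VALUES,
                      keep_default_na=False)
    numeric_cols = ["fc1", "fc2", "log2_fc2_fc1", "fc3", "fc4", "log2_fc4_fc3"]
    for col in numeric_cols:
        cleaned = raw[col].str.replace(_UNICODE_MINUS, "-", regex=False)
        raw[col] = pd.to_numeric(cleaned)
    return raw
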