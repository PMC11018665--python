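"""Readers and writers for the pipeline's table formats.

All tables are tab-separated UTF-8 with a ``.`` decimal separator; readers
are transparent to gzip (any path ending in ``.gz``).  The expression matrix
convention is genes in rows (first column = gene id) and samples in columns.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

CLADES = ("aerial", "underground", "pollen")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# expression / count matrices

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample TPM (or count) matrix from TSV.

    The first column holds gene ids and the header row sample ids; both must
    be unique and non-empty, the body must be numeric, non-missing and
    non-negative.
    """
    df = _read_tsv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    if any(not g for g in df.index):
        raise FormatError(f"empty gene id in {path}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric value in {path}: {exc}") from exc
    if values.isna().any().any():
        gene = values.index[values.isna().any(axis=1)][0]
        raise FormatError(f"missing value for gene {gene!r} in {path}")
    neg = values.values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"negative value {values.iat[i, j]} at gene {values.index[i]!r}, "
            f"sample {values.columns[j]!r} in {path}"
        )
    return values


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (columns sample_id, tissue[, clade])."""
    df = _read_tsv(path, dtype=str)
    required = {"sample_id", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata {path} lacks columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r} in {path}")
    if "clade" in df.columns:
        bad = set(df["clade"].dropna()) - set(CLADES)
        if bad:
            raise ValidationError(
                f"unknown clade value(s) {sorted(bad)} in {path}; "
                f"allowed: {list(CLADES)}"
            )
    return df.reset_index(drop=True)


def write_sample_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def check_samples_covered(matrix: pd.DataFrame, samples: pd.DataFrame) -> None:
    """Raise if a matrix sample is absent from the metadata table."""
    missing = sorted(set(matrix.columns) - set(samples["sample_id"]))
    if missing:
        raise ValidationError(f"samples missing from metadata: {missing}")


# ---------------------------------------------------------------------------
# mapping statistics

def read_mapping_stats(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"sample_id", "total_reads", "reads_after_trim",
                "mapped_pct", "uniquely_mapped_pct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"mapping stats {path} lacks columns {sorted(missing)}")
    for col in ("mapped_pct", "uniquely_mapped_pct"):
        vals = df[col].astype(float)
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError(f"{col} outside [0, 100] in {path}")
    if (df["reads_after_trim"].astype(float) > df["total_reads"].astype(float)).any():
        raise ValidationError(f"reads_after_trim exceeds total_reads in {path}")
    return df


# ---------------------------------------------------------------------------
# GO annotation

def read_go_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a gene -> GO-terms map.

    Accepts either a two-column TSV (gene_id, term id) or a GAF 2.x file
    (comment lines start with ``!``; the DB object id is column 2 and the GO
    id column 5, 1-based).
    """
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) >= 15:          # GAF 2.x body row
                gene, term = parts[1], parts[4]
            elif len(parts) >= 2:
                gene, term = parts[0], parts[1]
                if gene == "gene_id":     # optional header
                    continue
            else:
                raise FormatError(f"unparseable annotation line in {path}: {line!r}")
            if gene and term:
                mapping.setdefault(gene, set()).add(term)
                n_rows += 1
    if n_rows == 0:
        raise ValidationError(f"annotation file {path} contains no gene-term pairs")
    return {g: frozenset(t) for g, t in mapping.items()}


def write_go_map(go_map: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# network edge list / clusters

def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    """Write the network edge list (gene_a < gene_b lexicographically)."""
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"gene_a": str, "gene_b": str})
    required = {"gene_a", "gene_b", "pcc", "hrr"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"edge list {path} lacks columns {sorted(missing)}")
    return df


def write_clusters(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"gene_id": str, "cluster_id": str})
    missing = {"gene_id", "cluster_id"} - set(df.columns)
    if missing:
        raise FormatError(f"cluster table {path} lacks columns {sorted(missing)}")
    return df


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
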