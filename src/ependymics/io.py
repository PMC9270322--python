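"""Readers and writers for the plain-text formats used across the package.

Expression matrices are TSV with genes as rows and samples as columns,
gene sets travel as GMT, genomic intervals as BED6, sparse count matrices
as MatrixMarket (.mtx) with sidecar features/barcodes files, and ground
truth as JSON.
"""

from __future__ import annotations

import json
import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_expression_tsv(path: str) -> pd.DataFrame:
    """Read a genes x samples expression TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_labels_tsv(path: str) -> pd.Series:
    """Two-column TSV (identifier, label) -> Series indexed by identifier."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_labels_tsv(labels: pd.Series, path: str, index_label: str = "sample") -> None:
    labels.rename("label").to_csv(path, sep="\t", index_label=index_label)


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file (3-6 columns) into a DataFrame with BED6 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in [("name", "."), ("score", 0), ("strand", ".")]:
        if col not in df.columns:
            df[col] = default
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col, default in [("name", "."), ("score", 0), ("strand", ".")]:
        if col not in out.columns:
            out[col] = default
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_mtx_dir(matrix, features: Sequence[str], barcodes: Sequence[str],
                  outdir: str) -> None:
    """Write a features x barcodes matrix as matrix.mtx + features/barcodes TSVs."""
    os.makedirs(outdir, exist_ok=True)
    sp = scipy.sparse.csr_matrix(np.asarray(matrix))
    scipy.io.mmwrite(os.path.join(outdir, "matrix.mtx"), sp)
    pd.Series(list(features)).to_csv(
        os.path.join(outdir, "features.tsv"), sep="\t", header=False, index=False)
    pd.Series(list(barcodes)).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=False, index=False)


def read_mtx_dir(indir: str) -> pd.DataFrame:
    """Read a matrix.mtx + features.tsv + barcodes.tsv directory as a dense frame."""
    mat = scipy.io.mmread(os.path.join(indir, "matrix.mtx")).toarray()
    features = pd.read_csv(os.path.join(indir, "features.tsv"),
                           sep="\t", header=None).iloc[:, 0]
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"),
                           sep="\t", header=None).iloc[:, 0]
    return pd.DataFrame(mat, index=features, columns=barcodes)


def read_gene_loci_tsv(path: str) -> pd.DataFrame:
    """TSV with columns gene, chrom, start, end, strand, tss."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene loci file missing columns: {sorted(missing)}")
    return df


def read_enhancer_map_tsv(path: str) -> pd.DataFrame:
    """TSV with columns chrom, start, end, gene (GeneHancer-style records)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"enhancer map missing columns: {sorted(missing)}")
    return df


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, tuple, np.ndarray)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
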