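"""Reading and writing 10x-style count triplets and gene category annotation.

A count matrix is held as an :class:`anndata.AnnData` with raw integer counts
in ``X`` (cells x genes, CSR), barcodes as ``obs_names``, gene symbols as
``var_names``, per-cell sample metadata in ``obs`` and per-gene category flags
(mitochondrial, ribosomal, hemoglobin, cell-cycle, excluded immediate-early)
as boolean columns in ``var``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

#: var columns used for gene category flags
FLAG_COLUMNS = ("mito", "ribo", "hemoglobin", "cell_cycle", "iexcl")

# Default symbol lists. Mouse mito/ribo genes follow fixed prefix conventions;
# hemoglobin, cell-cycle and immediate-early lists are editable defaults, not
# an asserted reference set.
DEFAULT_HEMOGLOBIN = ("Hba-a1", "Hba-a2", "Hbb-bs", "Hbb-bt")
DEFAULT_CELL_CYCLE = (
    "Mki67", "Top2a", "Ccnb1", "Ccna2", "Cdk1", "Mcm2", "Mcm3", "Pcna", "Birc5",
)
DEFAULT_IEXCL = ("Xist", "Fos", "Fosb", "Jun", "Junb", "Jund")


@dataclass(frozen=True)
class GeneAnnotations:
    """Gene category lists used by QC metrics and HVG exclusion.

    Mitochondrial and ribosomal genes are matched case-sensitively by symbol
    prefix; the remaining categories by exact symbol.
    """

    mito_prefixes: tuple[str, ...] = ("mt-",)
    ribo_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    hemoglobin_symbols: tuple[str, ...] = DEFAULT_HEMOGLOBIN
    cell_cycle_symbols: tuple[str, ...] = DEFAULT_CELL_CYCLE
    iexcl_symbols: tuple[str, ...] = DEFAULT_IEXCL


def _read_lines(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_counts_triplet(matrix_path: str, barcodes_path: str, features_path: str) -> ad.AnnData:
    """Read a MatrixMarket coordinate matrix plus barcode/feature sidecars.

    On-disk orientation may be either cells x genes or the 10x convention
    genes x cells; it is inferred from the sidecar line counts and normalised
    to cells x genes in memory.
    """
    mat = scipy.io.mmread(matrix_path)
    mat = sp.coo_matrix(mat)
    data = np.asarray(mat.data)
    if data.size and data.min() < 0:
        raise FormatError(f"{matrix_path}: negative entries are not valid counts")
    if data.size and not np.array_equal(data, np.floor(data)):
        raise FormatError(f"{matrix_path}: non-integer entries are not valid counts")

    barcodes = _read_lines(barcodes_path)
    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    n_b, n_f = len(barcodes), len(feature_rows)

    r, c = mat.shape
    if n_b == n_f and (r, c) == (n_b, n_f):
        oriented = mat.T  # ambiguous square: take the 10x convention, genes x cells
    elif (r, c) == (n_b, n_f):
        oriented = mat
    elif (r, c) == (n_f, n_b):
        oriented = mat.T  # 10x convention: genes x cells on disk
    else:
        raise FormatError(
            f"{matrix_path}: header declares {r}x{c} but sidecars have "
            f"{n_b} barcodes and {n_f} features"
        )

    if n_f and len(feature_rows[0]) >= 2:
        gene_ids = [row[0] for row in feature_rows]
        symbols = [row[1] for row in feature_rows]
    else:
        gene_ids = [row[0] for row in feature_rows]
        symbols = list(gene_ids)
    if len(set(barcodes)) != n_b:
        raise FormatError(f"{barcodes_path}: barcodes are not unique")
    if len(set(symbols)) != n_f:
        raise FormatError(f"{features_path}: gene symbols are not unique")

    X = sp.csr_matrix(oriented, dtype=np.int64)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame({"gene_id": gene_ids}, index=pd.Index(symbols, name="symbol")),
    )
    return adata


def write_counts_triplet(adata: ad.AnnData, out_dir: str) -> dict[str, str]:
    """Write ``matrix.mtx`` (genes x cells, 10x convention), ``barcodes.tsv``
    and ``features.tsv``. Round-trips exactly through :func:`read_counts_triplet`."""
    if adata.n_obs == 0:
        raise FormatError("refusing to write an empty cohort (zero cells)")
    validate_counts(adata)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "features": os.path.join(out_dir, "features.tsv"),
    }
    X = sp.coo_matrix(adata.X).astype(np.int64)
    scipy.io.mmwrite(paths["matrix"], X.T, field="integer", symmetry="general")
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    gene_ids = (
        adata.var["gene_id"].tolist() if "gene_id" in adata.var else list(adata.var_names)
    )
    with open(paths["features"], "w") as fh:
        for gid, sym in zip(gene_ids, adata.var_names):
            fh.write(f"{gid}\t{sym}\n")
    return paths


def validate_counts(adata: ad.AnnData) -> None:
    """Check the count-matrix invariants (non-negative integers, unique ids)."""
    X = adata.X
    data = X.data if sp.issparse(X) else np.asarray(X).ravel()
    if data.size and data.min() < 0:
        raise FormatError("count matrix has negative entries")
    if data.size and not np.array_equal(data, np.floor(data)):
        raise FormatError("count matrix has non-integer entries")
    if adata.obs_names.has_duplicates:
        raise FormatError("cell ids are not unique")
    if adata.var_names.has_duplicates:
        raise FormatError("gene ids are not unique")


def annotate_genes(adata: ad.AnnData, ann: GeneAnnotations | None = None) -> ad.AnnData:
    """Set boolean gene category flags in ``var`` by prefix/symbol match.

    Idempotent: reapplication with the same annotation lists rewrites the same
    flags. Unmatched lists simply produce empty flag sets.
    """
    ann = ann or GeneAnnotations()
    symbols = adata.var_names
    flags = {
        "mito": symbols.str.startswith(tuple(ann.mito_prefixes) or ("\0",)),
        "ribo": symbols.str.startswith(tuple(ann.ribo_prefixes) or ("\0",)),
        "hemoglobin": symbols.isin(ann.hemoglobin_symbols),
        "cell_cycle": symbols.isin(ann.cell_cycle_symbols),
        "iexcl": symbols.isin(ann.iexcl_symbols),
    }
    for col, values in flags.items():
        adata.var[col] = np.asarray(values, dtype=bool)
    return adata


def concatenate_samples(matrices: Sequence[ad.AnnData]) -> ad.AnnData:
    """Stack per-library count matrices cell-wise.

    All inputs must share an identical, identically ordered gene list (one
    reference annotation). Cell ids are made unique by prefixing with the
    library's ``sample`` label (or a positional ``s<i>`` fallback).
    """
    if not matrices:
        raise FormatError("no matrices to concatenate")
    ref = list(matrices[0].var_names)
    for i, m in enumerate(matrices[1:], start=1):
        if list(m.var_names) != ref:
            raise FormatError(f"gene list of input {i} differs from input 0")
    parts = []
    for i, m in enumerate(matrices):
        m = m.copy()
        if "sample" in m.obs:
            prefix = str(m.obs["sample"].iloc[0]) if m.n_obs else f"s{i}"
        else:
            prefix = f"s{i}"
            m.obs["sample"] = prefix
        m.obs_names = [f"{prefix}:{b}" for b in m.obs_names]
        parts.append(m)
    out = ad.concat(parts, axis=0, join="inner", merge="same")
    out.var = matrices[0].var.copy()
    if out.obs_names.has_duplicates:
        raise FormatError("cell ids are not unique after sample prefixing")
    return out
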