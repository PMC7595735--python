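"""Cell- and gene-level quality control.

All exclusion criteria are strict inequalities ("fewer than", "more than"),
so cells sitting exactly on a threshold are kept: a cell survives the first
round iff total_counts >= min_counts, detected genes >= min_genes,
hemoglobin counts <= max_hemoglobin and mitochondrial fraction <=
max_mito_fraction. Neuronal cells undergo a second, stricter depth filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError


@dataclass(frozen=True)
class QCThresholds:
    min_counts: int = 2000
    min_genes: int = 1000
    max_hemoglobin: int = 50
    max_mito_fraction: float = 0.15
    neuronal_min_counts: int = 3500
    neuronal_min_genes: int = 2200
    gene_min_count: int = 3
    gene_min_cells: int = 3

    def validate(self) -> None:
        fields = (
            self.min_counts, self.min_genes, self.max_hemoglobin,
            self.max_mito_fraction, self.neuronal_min_counts,
            self.neuronal_min_genes, self.gene_min_count, self.gene_min_cells,
        )
        if any(v < 0 for v in fields):
            raise ConfigurationError("QC thresholds must be non-negative")
        if self.neuronal_min_counts < self.min_counts or self.neuronal_min_genes < self.min_genes:
            raise ConfigurationError(
                "neuronal refilter thresholds must be at least the first-round thresholds"
            )


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def compute_cell_qc(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell QC metrics: total counts, detected genes, hemoglobin counts
    and mitochondrial fraction (defined as 0 for an all-zero cell).

    Requires mito/hemoglobin gene flags in ``var`` (see ``annotate_genes``).
    """
    for col in ("mito", "hemoglobin"):
        if col not in adata.var:
            raise ConfigurationError(
                f"gene flag {col!r} missing from var; run annotate_genes first"
            )
    X = adata.X
    if sp.issparse(X):
        X = X.tocsr()
        total = np.asarray(X.sum(axis=1)).ravel()
        n_genes = X.getnnz(axis=1)
        hgb = np.asarray(X[:, adata.var["hemoglobin"].to_numpy()].sum(axis=1)).ravel()
        mito = np.asarray(X[:, adata.var["mito"].to_numpy()].sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        total = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
        hgb = X[:, adata.var["hemoglobin"].to_numpy()].sum(axis=1)
        mito = X[:, adata.var["mito"].to_numpy()].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "total_counts": total.astype(np.int64),
            "n_genes": np.asarray(n_genes, dtype=np.int64),
            "hemoglobin_counts": hgb.astype(np.int64),
            "mito_fraction": mito_fraction,
        },
        index=adata.obs_names,
    )


def filter_cells(metrics: pd.DataFrame, t: QCThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask over cells under the first-round thresholds."""
    t = t or QCThresholds()
    t.validate()
    return (
        (metrics["total_counts"] >= t.min_counts)
        & (metrics["n_genes"] >= t.min_genes)
        & (metrics["hemoglobin_counts"] <= t.max_hemoglobin)
        & (metrics["mito_fraction"] <= t.max_mito_fraction)
    ).to_numpy()


def filter_genes(adata: ad.AnnData, t: QCThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask over genes: kept iff expressed with at least
    ``gene_min_count`` counts in at least ``gene_min_cells`` cells."""
    t = t or QCThresholds()
    t.validate()
    X = adata.X
    if sp.issparse(X):
        n_cells = np.asarray((X >= t.gene_min_count).sum(axis=0)).ravel()
    else:
        n_cells = (np.asarray(X) >= t.gene_min_count).sum(axis=0)
    return n_cells >= t.gene_min_cells


def neuronal_refilter(
    metrics: pd.DataFrame, neuronal_cells: np.ndarray, t: QCThresholds | None = None
) -> np.ndarray:
    """Second-round filter applied to neuronal cells only.

    ``neuronal_cells`` is a boolean mask over the rows of ``metrics``; the
    returned mask keeps the neuronal cells meeting the stricter depth
    thresholds (non-neuronal positions are False).
    """
    t = t or QCThresholds()
    t.validate()
    neuronal_cells = np.asarray(neuronal_cells, dtype=bool)
    keep = (
        (metrics["total_counts"] >= t.neuronal_min_counts)
        & (metrics["n_genes"] >= t.neuronal_min_genes)
    ).to_numpy()
    return neuronal_cells & keep
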