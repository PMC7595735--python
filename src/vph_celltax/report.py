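"""Small reporting utilities: depth summaries and the in-situ co-expression
percentage calculator used for pie-chart style worked examples."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import anndata as ad
import numpy as np
import scipy.sparse as sp


def coexpression_percentage(positive_count: int, total_count: int) -> float:
    """Percentage of double-positive cells, half-up rounded to one decimal.

    E.g. 176 of 197 counted cells -> 89.3.
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if positive_count < 0 or positive_count > total_count:
        raise ValueError("positive_count must lie in [0, total_count]")
    pct = Decimal(positive_count) * Decimal(100) / Decimal(total_count)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_depth(adata: ad.AnnData) -> tuple[float, float]:
    """(median UMIs per cell, median detected genes per cell).

    Medians over an even number of cells use the midpoint convention.
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    X = adata.X
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        n_genes = X.tocsr().getnnz(axis=1)
    else:
        X = np.asarray(X)
        totals = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
    return float(np.median(totals)), float(np.median(n_genes))
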