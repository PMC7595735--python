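"""Depth normalization and dispersion-based highly-variable-gene selection.

Normalization rescales each cell's counts to the median total across cells,
then log2-transforms with a pseudocount of one:

    value(c, g) = log2(1 + counts(c, g) / T_c * median(T))

where ``T_c`` is cell ``c``'s total count. HVG selection ranks genes by their
normalized dispersion: dispersion (variance / mean of the normalized values)
standardized within equal-frequency mean bins, after removing mitochondrial,
ribosomal, hemoglobin, cell-cycle and excluded immediate-early genes from
candidacy (they stay in the matrix for classification and marker scoring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .io_formats import FLAG_COLUMNS


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Return a copy with ``X`` on the log2 normalized scale.

    Raw counts are kept in ``layers["counts"]``, per-cell totals in
    ``obs["size_factor"]`` and the median total in ``uns["scale_target"]``.
    """
    X = adata.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    totals = X.sum(axis=1).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell {adata.obs_names[zero[0]]!r} has zero total counts; "
            "normalize expects a QC-filtered matrix"
        )
    target = float(np.median(totals))
    values = np.log2(1.0 + X * (target / totals)[:, None])
    out = adata.copy()
    out.layers["counts"] = X
    out.X = values
    out.obs["size_factor"] = totals
    out.uns["scale_target"] = target
    return out


@dataclass
class HVGSelection:
    """Outcome of highly-variable-gene selection."""

    table: pd.DataFrame  # per gene: mean, dispersion, normalized_dispersion, excluded, selected
    selected: list[str]  # ordered, most variable first
    n_hvg: int
    n_bins: int
    excluded_categories: tuple[str, ...]


def select_hvgs(
    norm: ad.AnnData,
    n_hvg: int = 1500,
    n_bins: int = 20,
    exclude_flags: tuple[str, ...] = FLAG_COLUMNS,
    use_normalized_dispersion: bool = True,
) -> HVGSelection:
    """Pick the ``n_hvg`` most variable genes by (bin-standardized) dispersion.

    Ties are broken by higher raw dispersion, then lexicographic gene id.
    If fewer eligible genes exist than requested, all are returned with a
    warning.
    """
    X = norm.X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    df = pd.DataFrame(
        {"mean": mean, "dispersion": dispersion}, index=norm.var_names.copy()
    )
    missing = [f for f in exclude_flags if f not in norm.var]
    if missing:
        raise ConfigurationError(
            f"gene flags {missing} missing from var; run annotate_genes first"
        )
    excluded = np.zeros(X.shape[1], dtype=bool)
    for f in exclude_flags:
        excluded |= norm.var[f].to_numpy(dtype=bool)
    df["excluded"] = excluded

    nonzero = df["mean"] > 0
    if nonzero.sum() < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes with nonzero mean")
    if use_normalized_dispersion:
        bins = pd.qcut(df.loc[nonzero, "mean"], q=n_bins, duplicates="drop", labels=False)
        z = np.zeros(X.shape[1])
        disp_nz = df.loc[nonzero, "dispersion"]
        for b in np.unique(bins):
            members = nonzero.to_numpy().copy()
            members[nonzero.to_numpy()] = (bins == b).to_numpy()
            d = df.loc[members, "dispersion"]
            s = d.std(ddof=1)
            if not np.isfinite(s) or s == 0:
                z[members] = 0.0
            else:
                z[members] = (d - d.mean()) / s
        df["normalized_dispersion"] = z
    else:
        df["normalized_dispersion"] = df["dispersion"]

    eligible = df.loc[~df["excluded"]].copy()
    eligible = eligible.sort_values(
        by=["normalized_dispersion", "dispersion"],
        ascending=[False, False],
        kind="stable",
    )
    # lexicographic gene-id tiebreak after the two dispersion keys
    eligible["_gene"] = eligible.index
    eligible = eligible.sort_values(
        by=["normalized_dispersion", "dispersion", "_gene"],
        ascending=[False, False, True],
        kind="stable",
    )
    if len(eligible) < n_hvg:
        warnings.warn(
            f"only {len(eligible)} eligible genes for n_hvg={n_hvg}; returning all"
        )
    selected = eligible.index[:n_hvg].tolist()
    df["selected"] = df.index.isin(selected)
    return HVGSelection(
        table=df,
        selected=selected,
        n_hvg=n_hvg,
        n_bins=n_bins,
        excluded_categories=tuple(exclude_flags),
    )
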