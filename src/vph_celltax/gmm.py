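"""Gaussian-mixture assignment of clusters to cell classes.

Two fits are provided: a two-component mixture on per-cluster summaries of
four pan-neuronal genes (Snap25/Syp/Tubb3/Elavl2 by default) separating
neuronal from non-neuronal clusters, and a three-component mixture on four
neurotransmitter genes (Slc17a6/Slc32a1/Gad1/Hdc) naming neuronal clusters
glutamatergic, GABAergic or histaminergic. Components are named by rule, not
index: the neuronal component is the one with the larger mean-vector norm;
HA is the component with the largest Hdc mean, GLUT the largest Slc17a6 mean
among the rest, GABA the remainder.

Mixtures are fit in the full summary space with diagonal covariances and a
covariance floor (one observation per cluster makes full covariances
unstable), via EM with several k-means-seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.mixture import GaussianMixture

from .cluster import ClusterLabels
from .errors import AmbiguousMappingError, DegenerateFitError

#: EM settings recorded in fit metadata
COV_FLOOR = 1e-4
N_RESTARTS = 10
MAX_ITER = 500
TOL = 1e-8


@dataclass(frozen=True)
class ClassSignature:
    neuronal_genes: tuple[str, ...] = ("Snap25", "Syp", "Tubb3", "Elavl2")
    nt_genes: tuple[str, ...] = ("Slc17a6", "Slc32a1", "Gad1", "Hdc")
    summary_stat: str = "median"  # or "mean"


@dataclass
class GmmClassification:
    labels: pd.Series  # cluster id -> class name
    responsibilities: pd.DataFrame  # cluster x class
    component_means: pd.DataFrame  # class x gene
    component_covariances: pd.DataFrame  # class x gene (diagonal)
    weights: pd.Series  # class -> mixture weight
    class_names: list[str]
    meta: dict = field(default_factory=dict)
    _model: GaussianMixture | None = None


def summarize_cluster_expression(
    norm: ad.AnnData,
    labels: ClusterLabels,
    genes: Sequence[str],
    stat: str = "median",
) -> pd.DataFrame:
    """Cluster x gene summary (median or mean) of normalized expression."""
    if stat not in ("median", "mean"):
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")
    missing = [g for g in genes if g not in norm.var_names]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    X = norm[:, list(genes)].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    lab = np.asarray(labels.labels)
    rows = []
    for c in range(labels.K):
        mask = lab == c
        if not mask.any():
            raise ValueError(f"cluster {c} is empty")
        rows.append(np.median(X[mask], axis=0) if stat == "median" else X[mask].mean(axis=0))
    return pd.DataFrame(rows, index=pd.RangeIndex(labels.K, name="cluster"), columns=list(genes))


def _fit_mixture(summary: pd.DataFrame, n_components: int, seed: int) -> GaussianMixture:
    X = summary.to_numpy(dtype=float)
    if np.allclose(X, X[0], atol=1e-12):
        raise DegenerateFitError(
            "all cluster summaries are identical; the mixture is unidentifiable"
        )
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        reg_covar=COV_FLOOR,
        n_init=N_RESTARTS,
        init_params="kmeans",
        max_iter=MAX_ITER,
        tol=TOL,
        random_state=seed,
    )
    gm.fit(X)
    return gm


def _argmax_unique(values: np.ndarray, context: str) -> int:
    top = np.flatnonzero(values == values.max())
    if len(top) > 1:
        raise AmbiguousMappingError(
            f"{context}: components {top.tolist()} tie with means {values[top].tolist()}"
        )
    return int(top[0])


def _package(
    summary: pd.DataFrame,
    gm: GaussianMixture,
    comp_to_class: dict[int, str],
    class_names: list[str],
    seed: int,
) -> GmmClassification:
    resp = gm.predict_proba(summary.to_numpy(dtype=float))
    # per-cluster label by maximum responsibility; ties go to the lower index
    comp = resp.argmax(axis=1)
    labels = pd.Series(
        [comp_to_class[c] for c in comp], index=summary.index, name="class"
    )
    order = sorted(range(gm.n_components), key=lambda c: class_names.index(comp_to_class[c]))
    return GmmClassification(
        labels=labels,
        responsibilities=pd.DataFrame(
            resp[:, order], index=summary.index, columns=[comp_to_class[c] for c in order]
        ),
        component_means=pd.DataFrame(
            gm.means_[order], index=[comp_to_class[c] for c in order], columns=summary.columns
        ),
        component_covariances=pd.DataFrame(
            gm.covariances_[order], index=[comp_to_class[c] for c in order], columns=summary.columns
        ),
        weights=pd.Series(gm.weights_[order], index=[comp_to_class[c] for c in order]),
        class_names=class_names,
        meta={
            "n_iter": int(gm.n_iter_),
            "log_likelihood": float(gm.lower_bound_),
            "converged": bool(gm.converged_),
            "seed": seed,
            "cov_floor": COV_FLOOR,
            "n_restarts": N_RESTARTS,
            "max_iter": MAX_ITER,
            "tol": TOL,
            "component_order": order,
        },
        _model=gm,
    )


def classify_neuronal(summary: pd.DataFrame, seed: int = 0) -> GmmClassification:
    """Two-component mixture on pan-neuronal summaries; the component with the
    larger mean-vector norm is 'neuronal'."""
    if len(summary) < 3:
        raise ValueError("need at least 3 clusters to fit the two-state mixture")
    gm = _fit_mixture(summary, 2, seed)
    norms = np.linalg.norm(gm.means_, axis=1)
    neuronal = _argmax_unique(norms, "neuronal component selection")
    comp_to_class = {neuronal: "neuronal", 1 - neuronal: "non-neuronal"}
    return _package(summary, gm, comp_to_class, ["neuronal", "non-neuronal"], seed)


def classify_neurotransmitter(summary: pd.DataFrame, seed: int = 0) -> GmmClassification:
    """Three-component mixture on (Slc17a6, Slc32a1, Gad1, Hdc)-style
    summaries of neuronal clusters, named HA -> GLUT -> GABA by rule."""
    if len(summary) < 4:
        raise ValueError("need at least 4 neuronal clusters to fit the three-class mixture")
    if summary.shape[1] != 4:
        raise ValueError("expected a 4-gene neurotransmitter summary")
    gm = _fit_mixture(summary, 3, seed)
    hdc_col, glut_col = 3, 0  # column order follows ClassSignature.nt_genes
    ha = _argmax_unique(gm.means_[:, hdc_col], "HA component selection")
    remaining = [c for c in range(3) if c != ha]
    glut_means = gm.means_[remaining, glut_col]
    glut = remaining[_argmax_unique(glut_means, "GLUT component selection")]
    gaba = next(c for c in range(3) if c not in (ha, glut))
    comp_to_class = {ha: "HA", glut: "GLUT", gaba: "GABA"}
    return _package(summary, gm, comp_to_class, ["GLUT", "GABA", "HA"], seed)


def classify_cells(
    norm: ad.AnnData,
    genes: Sequence[str],
    fitted: GmmClassification,
) -> pd.Series:
    """Label individual cells by maximum responsibility under a fitted
    cluster-level mixture evaluated at each cell's signature expression.

    Exact ties are broken toward the lower component index (argmax rule).
    """
    X = norm[:, list(genes)].X
    X = X.toarray() if sp.issparse(X) else np.asarray(X)
    gm = fitted._model
    order = fitted.meta["component_order"]
    logp = gm._estimate_weighted_log_prob(X.astype(float))[:, order]
    names = list(fitted.responsibilities.columns)
    idx = logp.argmax(axis=1)
    return pd.Series([names[i] for i in idx], index=norm.obs_names, name="class")
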