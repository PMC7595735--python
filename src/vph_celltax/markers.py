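"""One-vs-rest marker discovery and the marker-sufficiency experiment.

A gene is a marker candidate for cluster ``c`` when its mean log2-normalized
expression inside the cluster exceeds the mean outside by more than
``min_diff`` (2 log2-units by default). Each candidate is scored by the area
under the one-vs-rest ROC curve obtained by sweeping a rank threshold over
cells ordered by the gene's expression; the AUROC is computed through the
rank-sum (Mann-Whitney) identity with mid-rank tie handling, which equals
explicit ROC integration. Genes with AUROC > 0.8 pass.

The sufficiency experiment asks how small a marker panel suffices to recover
cluster identity: cells are split into stratified train/test halves, the
top-k AUROC markers per cluster are recomputed on the training half only,
and a seeded random-forest classifier restricted to the panel predicts the
held-out labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm as normal_dist
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .cluster import ClusterLabels
from .errors import ConfigurationError


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def auroc_score(values: np.ndarray, membership: np.ndarray) -> float:
    """One-vs-rest AUROC of ranking ``membership`` by ``values``.

    Mid-rank ties; rank-sum identity: AUROC = (R1 - n1(n1+1)/2) / (n1 n0).
    """
    values = np.asarray(values, dtype=float)
    membership = np.asarray(membership, dtype=bool)
    n1 = int(membership.sum())
    n0 = len(membership) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be nonempty")
    ranks = rankdata(values)
    r1 = ranks[membership].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def mean_diff_candidates(
    norm: ad.AnnData,
    labels: ClusterLabels,
    cluster: int,
    min_diff: float = 2.0,
) -> list[str]:
    """Genes whose in-cluster mean exceeds the out-of-cluster mean by
    strictly more than ``min_diff`` log2-units."""
    mask = np.asarray(labels.labels) == cluster
    if not mask.any():
        raise ValueError(f"cluster {cluster} is empty")
    if mask.all():
        raise ValueError(f"cluster {cluster} contains every cell; no out-group exists")
    X = _dense(norm.X)
    diff = X[mask].mean(axis=0) - X[~mask].mean(axis=0)
    return [g for g, d in zip(norm.var_names, diff) if d > min_diff]


@dataclass
class MarkerTable:
    """Per (cluster, gene) one-vs-rest statistics for all mean-diff candidates."""

    table: pd.DataFrame  # cluster, gene, n_c, mean_in, mean_out, mean_diff, auroc, passed
    min_diff: float
    auroc_pass: float

    def for_cluster(self, cluster: int) -> pd.DataFrame:
        return self.table[self.table["cluster"] == cluster]

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passed"]]


def rank_markers(
    norm: ad.AnnData,
    labels: ClusterLabels,
    min_diff: float = 2.0,
    auroc_pass: float = 0.8,
) -> MarkerTable:
    """Score every mean-diff candidate of every cluster.

    Within each cluster rows are ordered by AUROC descending, ties by mean
    difference then gene id.
    """
    if labels.K < 2:
        raise ValueError("need at least 2 clusters for one-vs-rest scoring")
    X = _dense(norm.X)
    lab = np.asarray(labels.labels)
    genes = np.asarray(norm.var_names)
    rows = []
    for c in range(labels.K):
        mask = lab == c
        n_c = int(mask.sum())
        mean_in = X[mask].mean(axis=0)
        mean_out = X[~mask].mean(axis=0)
        diff = mean_in - mean_out
        for j in np.flatnonzero(diff > min_diff):
            auroc = auroc_score(X[:, j], mask)
            rows.append(
                (c, genes[j], n_c, mean_in[j], mean_out[j], diff[j], auroc, auroc > auroc_pass)
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "gene", "n_c", "mean_in", "mean_out", "mean_diff", "auroc", "passed"],
    )
    if len(table):
        table = table.sort_values(
            by=["cluster", "auroc", "mean_diff", "gene"],
            ascending=[True, False, False, True],
            kind="stable",
        ).reset_index(drop=True)
    return MarkerTable(table=table, min_diff=min_diff, auroc_pass=auroc_pass)


def wilcoxon_cross_check(
    norm: ad.AnnData,
    labels: ClusterLabels,
    cluster: int,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank genes by the tie-corrected one-vs-rest rank-sum z statistic.

    Normal approximation to the Mann-Whitney U; positive z means enrichment
    in the cluster. Returns the ``top_n`` genes with statistic and two-sided p.
    """
    mask = np.asarray(labels.labels) == cluster
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need at least 2 cells")
    X = _dense(norm.X)
    n = n1 + n0
    ranks = rankdata(X, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n0 / 2.0
    # tie correction per gene: sum over tie groups of (t^3 - t)
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var_u > 0, (u - mean_u) / np.sqrt(np.maximum(var_u, 1e-300)), 0.0)
    p = 2.0 * normal_dist.sf(np.abs(z))
    out = pd.DataFrame(
        {"gene": np.asarray(norm.var_names), "z": z, "p_value": p, "u": u}
    ).sort_values(by=["z", "gene"], ascending=[False, True], kind="stable")
    return out.head(top_n).reset_index(drop=True)


def stratified_split(
    labels: ClusterLabels | np.ndarray,
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test partition, proportional per cluster.

    Per cluster the train count is ``round(train_fraction * size)`` (half-up),
    clamped so both sides receive at least one cell. A 1-cell cluster is an
    error.
    """
    lab = np.asarray(labels.labels if isinstance(labels, ClusterLabels) else labels)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(lab):
        idx = np.flatnonzero(lab == c)
        if len(idx) < 2:
            raise ValueError(f"cluster {c} has {len(idx)} cell(s); cannot split")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class Panel:
    genes: list[str]  # unique, sorted
    per_cluster: dict[int, list[str]]
    shortfall: dict[int, int]  # cluster -> number of missing candidates


def top_k_panel(
    norm: ad.AnnData,
    labels: ClusterLabels,
    k: int,
    min_diff: float = 2.0,
    auroc_pass: float = 0.8,
    marker_table: MarkerTable | None = None,
) -> Panel:
    """Union over clusters of the top-k genes by AUROC (post mean-diff gate).

    Clusters with fewer than k candidates contribute all of them and are
    recorded in ``shortfall``.
    """
    mt = marker_table or rank_markers(norm, labels, min_diff=min_diff, auroc_pass=auroc_pass)
    per_cluster: dict[int, list[str]] = {}
    shortfall: dict[int, int] = {}
    for c in range(labels.K):
        top = mt.for_cluster(c)["gene"].tolist()[:k]
        per_cluster[c] = top
        if len(top) < k:
            shortfall[c] = k - len(top)
    genes = sorted(set(g for gs in per_cluster.values() for g in gs))
    return Panel(genes=genes, per_cluster=per_cluster, shortfall=shortfall)


@dataclass
class SufficiencyResult:
    records: list[dict]  # per k: k, panel, panel_size, accuracy, per_cluster_accuracy, confusion
    ks: tuple[int, ...]
    train_fraction: float
    seed: int
    n_estimators: int

    def accuracies(self) -> pd.Series:
        return pd.Series(
            {r["k"]: r["accuracy"] for r in self.records}, name="accuracy"
        ).rename_axis("k")


def sufficiency_experiment(
    norm: ad.AnnData,
    labels: ClusterLabels,
    ks: Sequence[int] = (2, 3, 5, 10, 15, 20),
    train_fraction: float = 0.5,
    seed: int = 0,
    min_diff: float = 2.0,
    auroc_pass: float = 0.8,
    n_estimators: int = 100,
) -> SufficiencyResult:
    """Marker-panel sufficiency: per k, train a seeded random forest on the
    training half restricted to the top-k panel and score the held-out half.

    Panels are selected on the training split only, so the test half never
    leaks into marker choice. Deterministic given ``seed``.
    """
    lab = np.asarray(labels.labels)
    train_idx, test_idx = stratified_split(lab, train_fraction, seed)
    X = _dense(norm.X)
    gene_pos = {g: j for j, g in enumerate(norm.var_names)}

    train_labels = ClusterLabels(
        labels=lab[train_idx], K=labels.K, cell_ids=[str(i) for i in train_idx]
    )
    train_view = norm[train_idx]
    mt = rank_markers(train_view, train_labels, min_diff=min_diff, auroc_pass=auroc_pass)

    records = []
    for k in ks:
        panel = top_k_panel(
            train_view, train_labels, k, min_diff=min_diff,
            auroc_pass=auroc_pass, marker_table=mt,
        )
        if not panel.genes:
            raise ValueError(f"empty marker panel at k={k}")
        cols = [gene_pos[g] for g in panel.genes]
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
        clf.fit(X[np.ix_(train_idx, cols)], lab[train_idx])
        pred = clf.predict(X[np.ix_(test_idx, cols)])
        truth = lab[test_idx]
        all_classes = np.arange(labels.K)
        conf = confusion_matrix(truth, pred, labels=all_classes)
        per_cluster = {}
        for c in all_classes:
            n_c = conf[c].sum()
            per_cluster[int(c)] = float(conf[c, c] / n_c) if n_c else float("nan")
        records.append(
            {
                "k": int(k),
                "panel": list(panel.genes),
                "panel_size": len(panel.genes),
                "shortfall": dict(panel.shortfall),
                "accuracy": float(np.trace(conf) / conf.sum()),
                "per_cluster_accuracy": per_cluster,
                "confusion": conf,
            }
        )
    return SufficiencyResult(
        records=records,
        ks=tuple(int(k) for k in ks),
        train_fraction=train_fraction,
        seed=seed,
        n_estimators=n_estimators,
    )
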