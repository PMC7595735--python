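"""Dimensionality reduction, kNN graph construction and community detection.

The embedding chain mirrors the standard droplet scRNA-seq recipe: PCA on the
HVG-restricted, per-gene centered matrix (50 components), an optional batch
correction step in PC space, retention of the 15 components with the largest
variance ratios, an exact k = 15 cosine nearest-neighbor graph, and a
modularity-style community detection on the symmetrized graph (Leiden by
default, with a deterministic greedy-modularity reference backend).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import anndata as ad
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import cosine_distances

from .errors import ConfigurationError
from .normalize import HVGSelection, select_hvgs


@dataclass
class Embedding:
    coordinates: np.ndarray  # cells x components
    variance_ratio: np.ndarray  # per component, descending at construction
    cell_ids: list[str]
    batch_corrected: bool = False
    correction_params: dict = field(default_factory=dict)


@dataclass
class NeighborGraph:
    k: int
    indices: np.ndarray  # cells x k neighbor indices
    distances: np.ndarray  # cells x k cosine distances
    metric: str = "cosine"

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class ClusterLabels:
    labels: np.ndarray  # per-cell int in 0..K-1
    K: int
    cell_ids: list[str]
    method: str = "leiden"
    resolution: float = 1.0
    seed: int = 0
    parent: str | None = None  # lineage tag for subclustering


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def compute_pcs(
    norm: ad.AnnData, hvg: HVGSelection, n_components: int = 50
) -> Embedding:
    """PCA on the HVG-restricted, per-gene mean-centered matrix.

    Component signs are fixed by making each component's largest-magnitude
    gene loading positive, so the result is fully deterministic.
    """
    if len(hvg.selected) < n_components:
        raise ValueError(
            f"{len(hvg.selected)} HVGs cannot support n_components={n_components}"
        )
    X = _dense(norm[:, hvg.selected].X).astype(float)
    max_rank = min(X.shape[0], X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds matrix rank bound {max_rank}; reducing"
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    # sign convention: largest-magnitude loading positive per component
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    coords = coords * flip
    return Embedding(
        coordinates=coords,
        variance_ratio=pca.explained_variance_ratio_.copy(),
        cell_ids=list(norm.obs_names),
    )


def batch_correct(
    emb: Embedding,
    batch_labels: Sequence,
    method: str = "center",
    params: dict | None = None,
) -> Embedding:
    """Batch correction in PC space.

    ``"none"`` is the identity; ``"center"`` subtracts each batch's mean per
    component (the reference fallback); ``"external"`` delegates to a callable
    hook ``params["hook"](coordinates, batch_labels, **params["hook_kwargs"])``
    for integration methods such as Harmony, recording the parameters
    verbatim.
    """
    params = dict(params or {})
    batch_labels = np.asarray(batch_labels)
    if len(batch_labels) != emb.coordinates.shape[0]:
        raise ValueError("one batch label per cell is required")
    if method == "none":
        coords = emb.coordinates.copy()
    elif method == "center":
        coords = emb.coordinates.copy()
        for b in np.unique(batch_labels):
            mask = batch_labels == b
            if mask.sum() == 1:
                warnings.warn(f"batch {b!r} has a single cell; passed through uncentered")
                continue
            coords[mask] -= coords[mask].mean(axis=0)
    elif method == "external":
        hook: Callable | None = params.get("hook")
        if hook is None:
            raise ConfigurationError(
                "method 'external' requires a callable under params['hook']"
            )
        coords = np.asarray(hook(emb.coordinates, batch_labels, **params.get("hook_kwargs", {})))
    else:
        raise ConfigurationError(f"unknown batch correction method {method!r}")
    return Embedding(
        coordinates=coords,
        variance_ratio=emb.variance_ratio.copy(),
        cell_ids=list(emb.cell_ids),
        batch_corrected=method != "none",
        correction_params={"method": method, **{k: v for k, v in params.items() if k != "hook"}},
    )


def select_pcs(emb: Embedding, n_keep: int = 15) -> Embedding:
    """Retain the ``n_keep`` components with the largest variance ratios
    (ties resolved by original component order)."""
    if n_keep > len(emb.variance_ratio):
        raise ValueError("n_keep exceeds the number of components")
    order = np.argsort(-emb.variance_ratio, kind="stable")[:n_keep]
    order = np.sort(order)
    return Embedding(
        coordinates=emb.coordinates[:, order],
        variance_ratio=emb.variance_ratio[order],
        cell_ids=list(emb.cell_ids),
        batch_corrected=emb.batch_corrected,
        correction_params=dict(emb.correction_params),
    )


def build_knn(emb: Embedding, k: int = 15) -> NeighborGraph:
    """Exact k nearest neighbors per cell under cosine distance.

    Brute force all-pairs search; ties are broken by cell index. Zero vectors
    are nudged by a tiny constant so cosine distance stays defined.
    """
    coords = emb.coordinates.astype(float)
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, have {n}")
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        coords = coords.copy()
        coords[norms == 0] = 1e-12
    D = cosine_distances(coords)
    np.fill_diagonal(D, np.inf)  # no self-edges
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dist = np.take_along_axis(D, order, axis=1)
    return NeighborGraph(k=k, indices=order, distances=np.clip(dist, 0.0, 2.0))


def _symmetrized_edges(g: NeighborGraph) -> list[tuple[int, int]]:
    edges = set()
    for i in range(g.n_cells):
        for j in g.indices[i]:
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            edges.add((a, b))
    return sorted(edges)


def cluster_graph(
    g: NeighborGraph,
    resolution: float = 1.0,
    seed: int = 0,
    backend: str = "leiden",
) -> ClusterLabels:
    """Community detection on the symmetrized kNN graph.

    Backends: ``"leiden"`` (igraph + leidenalg, RB-configuration modularity)
    or ``"greedy"`` (networkx deterministic greedy modularity maximization).
    Communities are relabeled 0..K-1 by decreasing size, ties by smallest
    member index, so labels are reproducible across backends and runs.
    """
    edges = _symmetrized_edges(g)
    n = g.n_cells
    if backend == "leiden":
        import igraph
        import leidenalg

        graph = igraph.Graph(n=n, edges=edges)
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=-1,
        )
        raw = np.asarray(part.membership)
    elif backend == "greedy":
        import networkx as nx

        graph = nx.Graph()
        graph.add_nodes_from(range(n))
        graph.add_edges_from(edges)
        communities = nx.algorithms.community.greedy_modularity_communities(
            graph, resolution=resolution
        )
        raw = np.empty(n, dtype=int)
        for c, members in enumerate(communities):
            raw[sorted(members)] = c
    else:
        raise ConfigurationError(f"unknown clustering backend {backend!r}")

    labels = _canonical_labels(raw)
    return ClusterLabels(
        labels=labels,
        K=int(labels.max()) + 1,
        cell_ids=[str(i) for i in range(n)],
        method=backend,
        resolution=resolution,
        seed=seed,
    )


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel communities by decreasing size, ties by smallest member index."""
    ids, counts = np.unique(raw, return_counts=True)
    first = {c: int(np.argmax(raw == c)) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in raw], dtype=int)


@dataclass(frozen=True)
class ReductionParams:
    """Knobs of one embedding/clustering pass."""

    n_hvg: int = 1500
    n_bins: int = 20
    n_components: int = 50
    n_keep: int = 15
    k: int = 15
    resolution: float = 1.0
    backend: str = "leiden"
    batch_method: str = "center"
    batch_key: str = "batch"
    seed: int = 0


def reduce_and_cluster(
    norm: ad.AnnData, params: ReductionParams
) -> tuple[Embedding, NeighborGraph, ClusterLabels]:
    """Run HVG selection through community detection on a normalized matrix."""
    hvg = select_hvgs(norm, n_hvg=params.n_hvg, n_bins=params.n_bins)
    n_comp = min(params.n_components, len(hvg.selected))
    emb = compute_pcs(norm, hvg, n_components=n_comp)
    if params.batch_method != "none" and params.batch_key in norm.obs:
        emb = batch_correct(emb, norm.obs[params.batch_key].to_numpy(), params.batch_method)
    emb = select_pcs(emb, n_keep=min(params.n_keep, emb.coordinates.shape[1]))
    graph = build_knn(emb, k=params.k)
    labels = cluster_graph(
        graph, resolution=params.resolution, seed=params.seed, backend=params.backend
    )
    labels.cell_ids = list(norm.obs_names)
    return emb, graph, labels


def subcluster(
    norm: ad.AnnData,
    labels: ClusterLabels,
    target_clusters: Sequence[int],
    params: ReductionParams | None = None,
) -> ClusterLabels:
    """Rerun the embedding/clustering chain on the cells of selected clusters.

    Returns child labels over the subset, carrying the parent lineage tag.
    """
    params = params or ReductionParams()
    target_clusters = list(target_clusters)
    if not target_clusters:
        raise ValueError("target_clusters must be nonempty")
    present = set(np.unique(labels.labels))
    missing = [c for c in target_clusters if c not in present]
    if missing:
        raise ValueError(f"clusters {missing} not present in labels")
    mask = np.isin(labels.labels, target_clusters)
    if mask.sum() < params.k + 1:
        raise ValueError(
            f"subset of {int(mask.sum())} cells is smaller than k+1={params.k + 1}"
        )
    sub = norm[mask].copy()
    n_comp = min(params.n_components, int(mask.sum()) - 1)
    sub_params = replace(params, n_components=n_comp)
    _, _, child = reduce_and_cluster(sub, sub_params)
    child.parent = "+".join(str(c) for c in sorted(target_clusters))
    return child
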