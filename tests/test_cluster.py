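"""PCA, batch centering, exact cosine kNN, community detection, subclustering."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vph_celltax.cluster import (
    ClusterLabels,
    Embedding,
    NeighborGraph,
    ReductionParams,
    batch_correct,
    build_knn,
    cluster_graph,
    compute_pcs,
    select_pcs,
    subcluster,
)
from vph_celltax.errors import ConfigurationError
from vph_celltax.normalize import HVGSelection, normalize, select_hvgs

from conftest import make_counts


def _norm_fixture(X, genes=None):
    norm = normalize(make_counts(X, genes=genes))
    sel = select_hvgs(norm, n_hvg=X.shape[1], n_bins=min(5, X.shape[1]))
    return norm, sel


def test_rank_one_data_concentrates_variance():
    # one latent direction + tiny noise, planted directly on the log scale
    rng = np.random.default_rng(0)
    latent = rng.uniform(0.5, 5, size=(40, 1))
    load = rng.uniform(-1.5, 1.5, size=(1, 20))
    values = 3.0 + latent @ load + rng.normal(0, 0.01, (40, 20))
    norm = make_counts(np.zeros((40, 20)))
    norm.X = values
    sel = HVGSelection(table=None, selected=list(norm.var_names), n_hvg=20,
                       n_bins=1, excluded_categories=())
    emb = compute_pcs(norm, sel, n_components=5)
    assert emb.variance_ratio[0] > 0.99
    assert np.all(np.diff(emb.variance_ratio) <= 1e-12)
    # oracle: eigendecomposition of the covariance of the HVG matrix
    M = norm.X - norm.X.mean(axis=0)
    eig = np.linalg.eigvalsh(np.cov(M.T))[::-1]
    np.testing.assert_allclose(emb.variance_ratio[0], eig[0] / eig.sum(), rtol=1e-8)


def test_duplicated_dataset_same_directions():
    rng = np.random.default_rng(1)
    X = rng.poisson(8.0, (25, 15))
    norm, sel = _norm_fixture(X)
    emb1 = compute_pcs(norm, sel, n_components=4)
    norm2, sel2 = _norm_fixture(np.vstack([X, X]))
    emb2 = compute_pcs(norm2, sel2, n_components=4)
    np.testing.assert_allclose(emb1.coordinates, emb2.coordinates[:25], atol=1e-8)


def test_more_components_than_cells_reduces_with_warning():
    rng = np.random.default_rng(2)
    norm, sel = _norm_fixture(rng.poisson(5.0, (6, 12)))
    with pytest.warns(UserWarning, match="reducing"):
        emb = compute_pcs(norm, sel, n_components=10)
    assert emb.coordinates.shape[1] == 6


def _embedding(coords):
    coords = np.asarray(coords, dtype=float)
    vr = np.linspace(0.5, 0.1, coords.shape[1])
    vr = vr / vr.sum()
    return Embedding(coordinates=coords, variance_ratio=vr,
                     cell_ids=[str(i) for i in range(len(coords))])


def test_batch_center_aligns_offset_batches():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(30, 4))
    coords = np.vstack([base[:15], base[15:] + 5.0])
    labels = ["a"] * 15 + ["b"] * 15
    out = batch_correct(_embedding(coords), labels, "center")
    np.testing.assert_allclose(
        out.coordinates[:15].mean(axis=0), out.coordinates[15:].mean(axis=0), atol=1e-12
    )
    assert out.batch_corrected


def test_batch_methods_identity_and_errors():
    emb = _embedding(np.random.default_rng(4).normal(size=(10, 3)))
    same = batch_correct(emb, ["x"] * 10, "none")
    np.testing.assert_array_equal(same.coordinates, emb.coordinates)
    centered = batch_correct(emb, ["x"] * 10, "center")
    np.testing.assert_allclose(centered.coordinates, emb.coordinates - emb.coordinates.mean(axis=0))
    with pytest.raises(ConfigurationError):
        batch_correct(emb, ["x"] * 10, "bogus")
    with pytest.raises(ConfigurationError):
        batch_correct(emb, ["x"] * 10, "external")  # no hook configured
    hook = lambda c, b: c * 2.0
    doubled = batch_correct(emb, ["x"] * 10, "external", {"hook": hook})
    np.testing.assert_allclose(doubled.coordinates, emb.coordinates * 2)


def test_single_cell_batch_passes_through_with_warning():
    emb = _embedding(np.ones((3, 2)))
    with pytest.warns(UserWarning, match="single cell"):
        batch_correct(emb, ["a", "a", "b"], "center")


def test_select_pcs_prefix_and_identity():
    emb = _embedding(np.random.default_rng(5).normal(size=(12, 6)))
    kept = select_pcs(emb, 3)
    np.testing.assert_array_equal(kept.coordinates, emb.coordinates[:, :3])
    np.testing.assert_array_equal(kept.variance_ratio, emb.variance_ratio[:3])
    full = select_pcs(emb, 6)
    np.testing.assert_array_equal(full.coordinates, emb.coordinates)


def test_select_pcs_orders_by_variance_ratio():
    coords = np.random.default_rng(6).normal(size=(10, 3))
    emb = Embedding(coordinates=coords, variance_ratio=np.array([0.1, 0.5, 0.2]),
                    cell_ids=[str(i) for i in range(10)])
    kept = select_pcs(emb, 2)
    np.testing.assert_array_equal(kept.coordinates, coords[:, 1:3])


def test_knn_cosine_distance_values():
    coords = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
    g = build_knn(_embedding(coords), k=2)
    # identical direction -> distance 0; orthogonal -> distance 1
    assert g.distances[0][g.indices[0].tolist().index(1)] == pytest.approx(0.0, abs=1e-12)
    assert g.distances[0][g.indices[0].tolist().index(2)] == pytest.approx(1.0)


def test_knn_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    coords = rng.normal(size=(30, 5))
    g = build_knn(_embedding(coords), k=6)
    D = cdist(coords, coords, metric="cosine")
    np.fill_diagonal(D, np.inf)
    expected = np.argsort(D, axis=1, kind="stable")[:, :6]
    np.testing.assert_array_equal(g.indices, expected)


def test_knn_too_few_cells_raises():
    with pytest.raises(ValueError, match="k\\+1"):
        build_knn(_embedding(np.ones((5, 2))), k=5)


def _clique_graph():
    # two 8-cliques, no cross edges
    k = 7
    indices = np.zeros((16, k), dtype=int)
    for i in range(16):
        group = range(8) if i < 8 else range(8, 16)
        indices[i] = [j for j in group if j != i]
    return NeighborGraph(k=k, indices=indices, distances=np.zeros((16, k)))


@pytest.mark.parametrize("backend", ["leiden", "greedy"])
def test_two_cliques_give_two_communities(backend):
    labels = cluster_graph(_clique_graph(), backend=backend, seed=0)
    assert labels.K == 2
    assert len(set(labels.labels[:8])) == 1
    assert len(set(labels.labels[8:])) == 1


def test_uniform_graph_single_community():
    n, k = 10, 9
    indices = np.array([[j for j in range(n) if j != i] for i in range(n)])
    g = NeighborGraph(k=k, indices=indices, distances=np.zeros((n, k)))
    labels = cluster_graph(g, resolution=1.0, seed=0)
    assert labels.K == 1


def test_cluster_graph_deterministic_and_partition():
    rng = np.random.default_rng(8)
    coords = np.vstack([rng.normal(0, 0.1, (20, 3)) + m for m in ([0, 0, 5], [5, 0, 0])])
    g = build_knn(_embedding(coords), k=5)
    l1 = cluster_graph(g, seed=3)
    l2 = cluster_graph(g, seed=3)
    np.testing.assert_array_equal(l1.labels, l2.labels)
    assert np.array_equal(np.unique(l1.labels), np.arange(l1.K))
    with pytest.raises(ConfigurationError):
        cluster_graph(g, backend="bogus")


def _two_population_norm(seed=0, n=160):
    from vph_celltax.synthetic import SimulationSpec, simulate

    spec = SimulationSpec(
        n_cells=n, n_genes=80, n_clusters=2, markers_per_cluster=8,
        marker_log2_effect=4.0, cluster_lognormal_sigma=0.5,
        depth_batch_factors=(1.0, 1.0), seed=seed,
    )
    adata, truth = simulate(spec)
    return normalize(adata), truth


SUB_PARAMS = ReductionParams(n_hvg=40, n_bins=4, n_components=10, n_keep=10, k=10,
                             resolution=0.3)


def test_subcluster_recovers_planted_subpopulations():
    norm, truth = _two_population_norm()
    parent = ClusterLabels(labels=np.zeros(norm.n_obs, dtype=int), K=1,
                           cell_ids=list(norm.obs_names))
    child = subcluster(norm, parent, [0], SUB_PARAMS)
    assert child.K == 2
    assert child.parent == "0"
    # perfect agreement with the planted split up to label naming
    a, b = truth.true_cluster == 0, child.labels == child.labels[np.argmax(truth.true_cluster == 0)]
    assert (a == b).mean() > 0.95


def test_subcluster_homogeneous_population_stays_single():
    from vph_celltax.synthetic import SimulationSpec, simulate

    spec = SimulationSpec(n_cells=80, n_genes=80, n_clusters=1, markers_per_cluster=5,
                          depth_batch_factors=(1.0, 1.0), seed=1)
    norm = normalize(simulate(spec)[0])
    parent = ClusterLabels(labels=np.zeros(80, dtype=int), K=1, cell_ids=list(norm.obs_names))
    child = subcluster(norm, parent, [0], ReductionParams(
        n_hvg=40, n_bins=4, n_components=10, n_keep=10, k=10, resolution=0.3))
    assert child.K == 1


def test_subcluster_errors():
    norm, _ = _two_population_norm(n=40)
    parent = ClusterLabels(labels=np.zeros(40, dtype=int), K=1, cell_ids=list(norm.obs_names))
    with pytest.raises(ValueError, match="nonempty"):
        subcluster(norm, parent, [])
    with pytest.raises(ValueError, match="not present"):
        subcluster(norm, parent, [5])
    tiny = ClusterLabels(labels=np.r_[np.zeros(35, dtype=int), np.ones(5, dtype=int)],
                         K=2, cell_ids=list(norm.obs_names))
    with pytest.raises(ValueError, match="k\\+1"):
        subcluster(norm, tiny, [1], SUB_PARAMS)
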