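"""AUROC statistic, Wilcoxon cross-check, splitting and panel sufficiency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from vph_celltax.cluster import ClusterLabels
from vph_celltax.markers import (
    auroc_score,
    mean_diff_candidates,
    rank_markers,
    stratified_split,
    sufficiency_experiment,
    top_k_panel,
    wilcoxon_cross_check,
)
from vph_celltax.normalize import normalize

from conftest import make_counts


def _labels(lab):
    lab = np.asarray(lab)
    return ClusterLabels(labels=lab, K=int(lab.max()) + 1,
                         cell_ids=[str(i) for i in range(len(lab))])


def _norm_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    adata = make_counts(np.zeros_like(values), genes=genes)
    adata.X = values
    return adata


# -- auroc ------------------------------------------------------------------


def test_auroc_examples():
    assert auroc_score([5, 4, 3, 0, 1, 0], [1, 1, 1, 0, 0, 0]) == 1.0
    assert auroc_score([2, 2, 2, 2], [1, 1, 0, 0]) == 0.5
    # pair enumeration: members {3,1}, rest {2,0}: 3 of 4 pairs concordant
    assert auroc_score([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75
    with pytest.raises(ValueError, match="nonempty"):
        auroc_score([1, 2], [1, 1])


@given(
    values=st.lists(
        st.floats(-100, 100, allow_nan=False), min_size=4, max_size=20, unique=True
    ),
    n1=st.integers(1, 3),
)
def test_auroc_complement_symmetry(values, n1):
    m = np.zeros(len(values), dtype=bool)
    m[:n1] = True
    assert auroc_score(values, m) + auroc_score(values, ~m) == pytest.approx(1.0)


@given(
    values=st.lists(st.integers(0, 8), min_size=4, max_size=20),
    n1=st.integers(1, 3),
)
def test_auroc_invariant_under_increasing_transform(values, n1):
    values = np.asarray(values, dtype=float)
    m = np.zeros(len(values), dtype=bool)
    m[:n1] = True
    if m.all() or not m.any():
        return
    direct = auroc_score(values, m)
    transformed = auroc_score(np.exp(values / 3.0) + values, m)
    assert direct == pytest.approx(transformed, abs=1e-12)


def test_auroc_equals_roc_integration_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = rng.integers(4, 31)
        values = rng.integers(0, 6, n).astype(float)  # heavy ties
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, rng.integers(1, n), replace=False)] = True
        if m.all() or not m.any():
            continue
        assert auroc_score(values, m) == pytest.approx(
            roc_auc_score(m, values), abs=1e-12
        )


# -- candidates and ranking -------------------------------------------------


def test_mean_diff_gate_is_strict():
    norm = _norm_from([[3, 2.5, 1], [3, 2.5, 1], [0.5, 0.5, 1], [0.5, 0.5, 1]],
                      genes=["big", "exact", "flat"])
    labels = _labels([0, 0, 1, 1])
    cands = mean_diff_candidates(norm, labels, 0)
    assert cands == ["big"]  # diff 2.5 in, 2.0 exactly out, constant excluded
    with pytest.raises(ValueError, match="every cell"):
        mean_diff_candidates(norm, _labels([0, 0, 0, 0]), 0)


def test_rank_markers_disjoint_clusters_have_disjoint_tables():
    rng = np.random.default_rng(1)
    base = rng.normal(1.0, 0.05, (40, 6)).clip(0)
    base[:20, 0:2] += 4.0  # cluster 0 markers
    base[20:, 3:5] += 4.0  # cluster 1 markers
    norm = _norm_from(base, genes=["a0", "a1", "shared", "b0", "b1", "flat"])
    mt = rank_markers(norm, _labels([0] * 20 + [1] * 20))
    g0 = set(mt.for_cluster(0)["gene"])
    g1 = set(mt.for_cluster(1)["gene"])
    assert g0 == {"a0", "a1"} and g1 == {"b0", "b1"}
    assert mt.table["passed"].all()
    assert "flat" not in set(mt.table["gene"])
    # sorted by auroc desc within cluster
    for c in (0, 1):
        au = mt.for_cluster(c)["auroc"].to_numpy()
        assert (np.diff(au) <= 0).all()


def test_wilcoxon_perfect_separator_is_top_and_matches_scipy():
    values = np.array(
        [[5.0, 1.2], [6.0, 0.8], [7.0, 1.1], [0.0, 1.0], [1.0, 0.9], [2.0, 1.3]]
    )
    norm = _norm_from(values, genes=["sep", "noise"])
    labels = _labels([0, 0, 0, 1, 1, 1])
    out = wilcoxon_cross_check(norm, labels, 0, top_n=2)
    assert out.iloc[0]["gene"] == "sep"
    # scipy oracle for the U statistic and asymptotic p
    u_sep = mannwhitneyu(values[:3, 0], values[3:, 0], alternative="two-sided",
                         method="asymptotic", use_continuity=False)
    assert out.iloc[0]["u"] == u_sep.statistic
    assert out.iloc[0]["p_value"] == pytest.approx(u_sep.pvalue, rel=1e-9)


def test_wilcoxon_and_auroc_top_lists_agree_on_planted_markers():
    from vph_celltax.synthetic import SimulationSpec, simulate

    spec = SimulationSpec(n_cells=300, n_genes=100, n_clusters=2, markers_per_cluster=10,
                          marker_log2_effect=3.0, depth_batch_factors=(1.0, 1.0), seed=3)
    adata, truth = simulate(spec)
    norm = normalize(adata)
    labels = _labels(truth.true_cluster)
    top_w = set(wilcoxon_cross_check(norm, labels, 0, top_n=10)["gene"])
    mt = rank_markers(norm, labels)
    top_a = set(mt.for_cluster(0)["gene"].head(10))
    assert len(top_w & top_a) >= 8


# -- splitting and sufficiency ----------------------------------------------


def test_stratified_split_proportional():
    train, test = stratified_split(np.array([0, 0, 0, 0, 1, 1]), 0.5, seed=0)
    lab = np.array([0, 0, 0, 0, 1, 1])
    assert sorted(np.concatenate([train, test])) == list(range(6))
    assert (lab[train] == 0).sum() == 2 and (lab[train] == 1).sum() == 1


def test_stratified_split_rounds_half_up():
    lab = np.array([0] * 5 + [1] * 4)
    train, _ = stratified_split(lab, 0.5, seed=1)
    assert (lab[train] == 0).sum() == 3  # round(2.5) -> 3
    assert (lab[train] == 1).sum() == 2


def test_stratified_split_determinism_and_errors():
    lab = np.array([0] * 6 + [1] * 6)
    assert all(
        np.array_equal(a, b)
        for a, b in zip(stratified_split(lab, 0.5, 7), stratified_split(lab, 0.5, 7))
    )
    with pytest.raises(ValueError, match="cluster 1"):
        stratified_split(np.array([0, 0, 1]), 0.5, 0)


def test_top_k_panel_union_sharing_and_empty():
    rng = np.random.default_rng(2)
    base = rng.normal(1.0, 0.05, (60, 7)).clip(0)
    base[:20, 0:2] += 4.0
    base[20:40, 2:4] += 4.0
    base[40:, 4:6] += 4.0
    norm = _norm_from(base, genes=[f"m{j}" for j in range(7)])
    labels = _labels([0] * 20 + [1] * 20 + [2] * 20)
    panel = top_k_panel(norm, labels, 2)
    assert len(panel.genes) == 6 and not panel.shortfall
    assert top_k_panel(norm, labels, 0).genes == []
    # a marker shared between two clusters shrinks the union below k x K
    shared = rng.normal(1.0, 0.05, (60, 3)).clip(0)
    shared[:40, 0] += 20.0  # clusters 0 and 1 share their only candidate
    shared[40:, 1] += 4.0
    norm2 = _norm_from(shared, genes=["s", "c", "flat"])
    panel2 = top_k_panel(norm2, labels, 1)
    assert panel2.genes == ["c", "s"]  # 2 genes despite k x K = 3


def test_sufficiency_chance_level_on_shuffled_labels():
    from vph_celltax.synthetic import SimulationSpec, simulate

    spec = SimulationSpec(n_cells=400, n_genes=80, n_clusters=4, markers_per_cluster=5,
                          depth_batch_factors=(1.0, 1.0), seed=4)
    adata, truth = simulate(spec)
    norm = normalize(adata)
    rng = np.random.default_rng(0)
    shuffled = rng.permutation(truth.true_cluster)
    labels = _labels(shuffled)
    # mean-diff gate finds nothing against shuffled labels; lift it for the test
    res = sufficiency_experiment(norm, labels, ks=(3,), seed=0, min_diff=-1.0)
    freq = np.bincount(shuffled) / len(shuffled)
    assert res.records[0]["accuracy"] == pytest.approx(freq.max(), abs=0.06)


def test_sufficiency_accuracy_grows_with_k_and_is_deterministic():
    from vph_celltax.synthetic import SimulationSpec, simulate

    spec = SimulationSpec(n_cells=500, n_genes=120, n_clusters=5, markers_per_cluster=5,
                          marker_log2_effect=3.0, depth_batch_factors=(1.0, 1.0), seed=5)
    adata, truth = simulate(spec)
    norm = normalize(adata)
    labels = _labels(truth.true_cluster)
    res = sufficiency_experiment(norm, labels, ks=(1, 3, 5), seed=2)
    accs = res.accuracies()
    assert (accs.diff().dropna() >= -0.02).all()
    again = sufficiency_experiment(norm, labels, ks=(1, 3, 5), seed=2)
    assert accs.equals(again.accuracies())
    # confusion marginals conserve test-set cluster sizes
    _, test_idx = stratified_split(truth.true_cluster, 0.5, seed=2)
    sizes = np.bincount(truth.true_cluster[test_idx], minlength=5)
    for r in res.records:
        np.testing.assert_array_equal(r["confusion"].sum(axis=1), sizes)
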