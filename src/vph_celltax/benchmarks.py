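"""Standardized synthetic-cohort benchmark runs.

These wire the generator presets to the analysis stages in the two
configurations used for headline property checks: the marker-panel
sufficiency experiment on a neuronal-only cohort, and full-pipeline
recovery of the planted truth on the mixed cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cluster import ClusterLabels
from .markers import rank_markers, sufficiency_experiment
from .model import CellTaxonomy
from .normalize import normalize
from .qc import compute_cell_qc, filter_cells, filter_genes
from .synthetic import paper_regime_spec, simulate


def marker_sufficiency_run(
    scale: float = 0.1,
    gen_seed: int = 7,
    clf_seed: int = 7,
    ks: tuple[int, ...] = (2,),
    train_fraction: float = 0.5,
) -> list[dict]:
    """Sufficiency experiment on a neuronal-only planted cohort.

    Generates the 20-cluster neuronal regime at ``scale``, applies cell and
    gene QC, normalizes, and runs the top-k marker-panel classification
    against the planted cluster labels. Returns the per-k records augmented
    with the cohort size.
    """
    spec = paper_regime_spec(scale, neuronal_only=True, seed=gen_seed)
    adata, _ = simulate(spec)
    keep = filter_cells(compute_cell_qc(adata))
    sub = adata[keep].copy()
    sub = sub[:, filter_genes(sub)].copy()
    norm = normalize(sub)
    lab = sub.obs["true_cluster"].to_numpy()
    labels = ClusterLabels(labels=lab, K=spec.n_clusters, cell_ids=list(sub.obs_names))
    res = sufficiency_experiment(
        norm, labels, ks=ks, train_fraction=train_fraction, seed=clf_seed
    )
    out = []
    for r in res.records:
        r = dict(r)
        r["n_cells"] = int(sub.n_obs)
        out.append(r)
    return out


@dataclass
class TruthRecovery:
    """Full-pipeline recovery diagnostics against the planted truth."""

    qc_exact: bool  # kept cells == non-QC-fail cells
    ari: float  # adjusted Rand index, round-1 clusters vs planted
    recovered_K: int
    planted_K: int
    class_all_correct: bool  # per-cluster neuronal/non-neuronal classing
    marker_cluster_pass: list[bool]  # per planted cluster: all markers pass


def truth_recovery_run(scale: float = 0.05, seed: int = 1) -> TruthRecovery:
    spec = paper_regime_spec(scale, seed=seed)
    model = CellTaxonomy.from_simulation(spec)
    res = model.fit(seed=seed)
    truth = model.truth

    qc_exact = bool(np.array_equal(res.kept_cells, ~truth.qc_fail))
    tc = res.norm.obs["true_cluster"].to_numpy()
    ari = float(adjusted_rand_score(tc, res.clusters.labels))

    # per recovered cluster: does the mixture class match the planted majority?
    df = pd.DataFrame(
        {
            "cluster": res.clusters.labels,
            "true_class": res.norm.obs["true_class"].to_numpy(),
        }
    )
    majority = df.groupby("cluster")["true_class"].agg(lambda s: s.mode().iloc[0])
    class_all_correct = bool((res.neuronal_fit.labels == majority).all())

    # planted markers scored one-vs-rest against the planted clusters
    true_labels = ClusterLabels(
        labels=tc, K=spec.n_clusters, cell_ids=list(res.norm.obs_names)
    )
    mt = rank_markers(res.norm, true_labels)
    passing = mt.passing()
    marker_pass = []
    for c, genes in truth.marker_map.items():
        present = [g for g in genes if g in res.norm.var_names]
        cluster_pass = set(passing[passing["cluster"] == c]["gene"])
        marker_pass.append(all(g in cluster_pass for g in present))

    return TruthRecovery(
        qc_exact=qc_exact,
        ari=ari,
        recovered_K=res.clusters.K,
        planted_K=spec.n_clusters,
        class_all_correct=class_all_correct,
        marker_cluster_pass=marker_pass,
    )
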