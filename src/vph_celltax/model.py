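"""End-to-end taxonomy model in the Model/Results idiom.

``CellTaxonomy`` is constructed from a raw count matrix (an AnnData with
per-cell sample/sex/batch metadata) plus a :class:`PipelineConfig`; ``fit``
executes the full chain -- per-library cell QC, gene filtering, depth
normalization, HVG selection, PCA with batch correction, cosine kNN graph,
community detection, two-state mixture classing of clusters into neuronal vs
non-neuronal, the stricter neuronal refilter, separate re-clustering of the
neuronal and non-neuronal compartments, three-class neurotransmitter
classing, one-vs-rest AUROC marker discovery and (optionally) the
marker-sufficiency experiment -- and returns a ``CellTaxonomyResults``
carrying every intermediate artifact, a stage-by-stage run manifest and a
``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import json
import os
import time
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import qc as qc_mod
from .cluster import ClusterLabels, Embedding, ReductionParams, reduce_and_cluster
from .errors import EmptyCohortError, StageError
from .gmm import (
    ClassSignature,
    GmmClassification,
    classify_neuronal,
    classify_neurotransmitter,
    summarize_cluster_expression,
)
from .io_formats import GeneAnnotations, annotate_genes, validate_counts
from .markers import MarkerTable, SufficiencyResult, rank_markers, sufficiency_experiment
from .normalize import normalize
from .report import summarize_depth


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of one run; defaults follow the standard
    droplet scRNA-seq recipe this pipeline implements."""

    thresholds: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    annotations: GeneAnnotations = field(default_factory=GeneAnnotations)
    signature: ClassSignature = field(default_factory=ClassSignature)
    n_hvg: int = 1500
    n_bins: int = 20
    n_components: int = 50
    n_keep: int = 15
    k: int = 15
    resolution: float = 1.0
    backend: str = "leiden"
    batch_method: str = "center"
    batch_key: str = "batch"
    # recorded defaults for an external integration hook (e.g. Harmony)
    external_params: dict = field(
        default_factory=lambda: {"theta_chemistry": 2.0, "theta_sex": 0.5}
    )
    min_diff: float = 2.0
    auroc_pass: float = 0.8
    ks: tuple[int, ...] = (2, 3, 5, 10, 15, 20)
    train_fraction: float = 0.5
    run_sufficiency: bool = False
    seed: int = 0

    def reduction_params(self, seed: int) -> ReductionParams:
        return ReductionParams(
            n_hvg=self.n_hvg,
            n_bins=self.n_bins,
            n_components=self.n_components,
            n_keep=self.n_keep,
            k=self.k,
            resolution=self.resolution,
            backend=self.backend,
            batch_method=self.batch_method,
            batch_key=self.batch_key,
            seed=seed,
        )


@dataclass
class RunManifest:
    """Auditable record of one run: config snapshot, per-stage dimensions
    and seeds."""

    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    started: float = field(default_factory=time.time)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "time": time.time(), **info})

    def to_json(self, path: str) -> None:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=default)


@dataclass
class LineageResult:
    """Re-clustering artifacts of one compartment (neuronal / non-neuronal)."""

    name: str
    norm: ad.AnnData
    embedding: Embedding
    labels: ClusterLabels
    markers: MarkerTable


class CellTaxonomy:
    """Taxonomy model over a raw count matrix.

    Parameters
    ----------
    counts
        AnnData of raw integer counts (cells x genes) with ``sample``/``sex``/
        ``batch`` columns in ``obs`` where available.
    config
        Pipeline parameters; defaults are used when omitted.
    """

    def __init__(self, counts: ad.AnnData, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        validate_counts(counts)
        self.counts = counts.copy()
        annotate_genes(self.counts, self.config.annotations)

    @classmethod
    def from_triplet(
        cls,
        matrix_path: str,
        barcodes_path: str,
        features_path: str,
        config: PipelineConfig | None = None,
    ) -> "CellTaxonomy":
        from .io_formats import read_counts_triplet

        return cls(read_counts_triplet(matrix_path, barcodes_path, features_path), config)

    @classmethod
    def from_simulation(cls, spec, config: PipelineConfig | None = None) -> "CellTaxonomy":
        from .synthetic import simulate

        adata, truth = simulate(spec)
        model = cls(adata, config)
        model.truth = truth
        return model

    # -- fitting ---------------------------------------------------------

    def fit(self, seed: int | None = None) -> "CellTaxonomyResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        manifest = RunManifest(config=_config_dict(cfg), seed=seed)
        res = CellTaxonomyResults(model=self, manifest=manifest, seed=seed)

        def stage(name):
            def runner(fn, *args, **kwargs):
                try:
                    return fn(*args, **kwargs)
                except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                    raise StageError(name, exc) from exc
            return runner

        # 1. QC: cell filters per library, gene filter on the aggregate
        run = stage("qc")
        metrics = run(qc_mod.compute_cell_qc, self.counts)
        keep_cells = run(qc_mod.filter_cells, metrics, cfg.thresholds)
        if not keep_cells.any():
            raise StageError("qc", EmptyCohortError("no cells survive the QC thresholds"))
        filtered = self.counts[keep_cells].copy()
        keep_genes = run(qc_mod.filter_genes, filtered, cfg.thresholds)
        filtered = filtered[:, keep_genes].copy()
        res.qc_metrics = metrics
        res.kept_cells = keep_cells
        res.kept_genes = keep_genes
        res.filtered_counts = filtered
        med_umi, med_genes = summarize_depth(filtered)
        manifest.record(
            "qc",
            n_cells_in=self.counts.n_obs,
            n_cells_out=filtered.n_obs,
            n_genes_in=self.counts.n_vars,
            n_genes_out=filtered.n_vars,
            median_umis=med_umi,
            median_genes=med_genes,
            gene_filter_reading="keep genes with >=gene_min_count counts in >=gene_min_cells cells",
        )

        # 2. normalization
        res.norm = stage("normalize")(normalize, filtered)
        manifest.record("normalize", scale_target=res.norm.uns["scale_target"])

        # 3. round-1 embedding + clustering
        emb, graph, labels = stage("cluster")(
            reduce_and_cluster, res.norm, cfg.reduction_params(seed)
        )
        res.embedding, res.graph, res.clusters = emb, graph, labels
        manifest.record(
            "cluster", n_cells=res.norm.n_obs, K=labels.K,
            backend=cfg.backend, resolution=cfg.resolution, seed=seed,
        )

        # 4. neuronal vs non-neuronal classing of round-1 clusters
        run = stage("classify_neuronal")
        summary = run(
            summarize_cluster_expression,
            res.norm, labels, cfg.signature.neuronal_genes, cfg.signature.summary_stat,
        )
        res.neuronal_fit = run(classify_neuronal, summary, seed + 1)
        cell_class = res.neuronal_fit.labels.loc[labels.labels].to_numpy()
        res.cell_class = pd.Series(cell_class, index=res.norm.obs_names, name="class")
        n_neuronal_clusters = int((res.neuronal_fit.labels == "neuronal").sum())
        manifest.record(
            "classify_neuronal",
            n_neuronal_clusters=n_neuronal_clusters,
            n_nonneuronal_clusters=labels.K - n_neuronal_clusters,
        )

        # 5. neuronal refilter on the stricter depth thresholds
        run = stage("neuronal_refilter")
        metrics2 = run(qc_mod.compute_cell_qc, filtered)
        neuronal_mask = (res.cell_class == "neuronal").to_numpy()
        keep_neuronal = run(qc_mod.neuronal_refilter, metrics2, neuronal_mask, cfg.thresholds)
        res.neuronal_mask = keep_neuronal
        res.nonneuronal_mask = ~neuronal_mask
        manifest.record(
            "neuronal_refilter",
            n_neuronal_in=int(neuronal_mask.sum()),
            n_neuronal_out=int(keep_neuronal.sum()),
        )

        # 6. separate re-analysis of each compartment
        res.lineages = {}
        for name, mask, lineage_seed in (
            ("neuronal", keep_neuronal, seed + 10),
            ("non-neuronal", res.nonneuronal_mask, seed + 20),
        ):
            if mask.sum() < cfg.k + 1:
                manifest.record(f"recluster_{name}", skipped=True, n_cells=int(mask.sum()))
                continue
            run = stage(f"recluster_{name}")
            sub_norm = run(normalize, filtered[mask].copy())
            sub_emb, _, sub_labels = run(
                reduce_and_cluster, sub_norm, cfg.reduction_params(lineage_seed)
            )
            sub_markers = run(
                rank_markers, sub_norm, sub_labels, cfg.min_diff, cfg.auroc_pass
            ) if sub_labels.K >= 2 else MarkerTable(pd.DataFrame(), cfg.min_diff, cfg.auroc_pass)
            res.lineages[name] = LineageResult(
                name=name, norm=sub_norm, embedding=sub_emb,
                labels=sub_labels, markers=sub_markers,
            )
            manifest.record(
                f"recluster_{name}", n_cells=sub_norm.n_obs, K=sub_labels.K,
                n_marker_rows=len(sub_markers.table),
            )

        # 7. neurotransmitter classing of the re-clustered neuronal compartment
        neuronal = res.lineages.get("neuronal")
        if neuronal is not None and neuronal.labels.K >= 4:
            run = stage("classify_nt")
            nt_summary = run(
                summarize_cluster_expression,
                neuronal.norm, neuronal.labels,
                cfg.signature.nt_genes, cfg.signature.summary_stat,
            )
            res.nt_fit = run(classify_neurotransmitter, nt_summary, seed + 2)
            manifest.record(
                "classify_nt",
                classes=res.nt_fit.labels.value_counts().to_dict(),
            )

        # 8. optional marker-sufficiency experiment on the neuronal compartment
        if cfg.run_sufficiency and neuronal is not None and neuronal.labels.K >= 2:
            res.sufficiency = stage("sufficiency")(
                sufficiency_experiment,
                neuronal.norm, neuronal.labels,
                cfg.ks, cfg.train_fraction, seed + 3, cfg.min_diff, cfg.auroc_pass,
            )
            manifest.record(
                "sufficiency",
                accuracies={r["k"]: r["accuracy"] for r in res.sufficiency.records},
            )

        return res


@dataclass
class CellTaxonomyResults:
    """Artifacts of one fitted taxonomy run."""

    model: CellTaxonomy
    manifest: RunManifest
    seed: int
    qc_metrics: pd.DataFrame | None = None
    kept_cells: np.ndarray | None = None
    kept_genes: np.ndarray | None = None
    filtered_counts: ad.AnnData | None = None
    norm: ad.AnnData | None = None
    embedding: Embedding | None = None
    graph: object | None = None
    clusters: ClusterLabels | None = None
    neuronal_fit: GmmClassification | None = None
    cell_class: pd.Series | None = None
    neuronal_mask: np.ndarray | None = None
    nonneuronal_mask: np.ndarray | None = None
    lineages: dict = field(default_factory=dict)
    nt_fit: GmmClassification | None = None
    sufficiency: SufficiencyResult | None = None

    def summary(self) -> str:
        """Human-readable run summary, one line per stage."""
        lines = ["CellTaxonomy run summary", "========================"]
        for s in self.manifest.stages:
            info = ", ".join(
                f"{k}={v}" for k, v in s.items() if k not in ("stage", "time")
            )
            lines.append(f"{s['stage']:<22} {info}")
        if self.nt_fit is not None:
            counts = self.nt_fit.labels.value_counts().to_dict()
            lines.append(f"{'nt classes':<22} {counts}")
        if self.sufficiency is not None:
            accs = ", ".join(
                f"k={r['k']}: {r['accuracy']:.3f} ({r['panel_size']} genes)"
                for r in self.sufficiency.records
            )
            lines.append(f"{'sufficiency':<22} {accs}")
        return "\n".join(lines)

    def save(self, out_dir: str) -> None:
        """Write label tables, class tables, marker tables and the manifest."""
        os.makedirs(out_dir, exist_ok=True)
        self.manifest.to_json(os.path.join(out_dir, "manifest.json"))
        if self.clusters is not None:
            pd.DataFrame(
                {"cell_id": self.norm.obs_names, "cluster": self.clusters.labels,
                 "cell_class": self.cell_class.to_numpy()}
            ).to_csv(os.path.join(out_dir, "clusters.tsv"), sep="\t", index=False)
        for name, lineage in self.lineages.items():
            tag = name.replace("-", "_")
            pd.DataFrame(
                {"cell_id": lineage.norm.obs_names, "cluster": lineage.labels.labels}
            ).to_csv(os.path.join(out_dir, f"clusters_{tag}.tsv"), sep="\t", index=False)
            lineage.markers.table.to_csv(
                os.path.join(out_dir, f"markers_{tag}.tsv"), sep="\t", index=False
            )
        if self.neuronal_fit is not None:
            cls = self.neuronal_fit.labels.rename("class").rename_axis("cluster").reset_index()
            cls.to_csv(os.path.join(out_dir, "cluster_classes.tsv"), sep="\t", index=False)
        if self.nt_fit is not None:
            cls = self.nt_fit.labels.rename("class").rename_axis("cluster").reset_index()
            cls.to_csv(os.path.join(out_dir, "nt_classes.tsv"), sep="\t", index=False)
        if self.sufficiency is not None:
            with open(os.path.join(out_dir, "sufficiency.json"), "w") as fh:
                json.dump(
                    [
                        {k: v for k, v in r.items() if k != "confusion"}
                        for r in self.sufficiency.records
                    ],
                    fh, indent=2,
                )
            for r in self.sufficiency.records:
                pd.DataFrame(r["confusion"]).to_csv(
                    os.path.join(out_dir, f"confusion_k{r['k']}.csv"), index=False
                )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def run_pipeline(
    counts: ad.AnnData, config: PipelineConfig | None = None, out_dir: str | None = None
) -> CellTaxonomyResults:
    """Convenience wrapper: fit the taxonomy and optionally save artifacts."""
    model = CellTaxonomy(counts, config)
    results = model.fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
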