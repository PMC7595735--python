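"""Synthetic count-matrix generator with planted ground truth.

Counts follow a negative-binomial model: gene ``g`` in a cell of cluster ``c``
has mean ``baseline_mean * 2^(marker_log2_effect * 1[g in markers(c)]) *
depth_factor(batch)``, with variance ``mu + alpha * mu^2`` (``alpha`` =
``nb_dispersion``, shared across genes). Clusters declared neuronal
additionally elevate four pan-neuronal signature genes (Snap25/Syp/Tubb3/
Elavl2 analogs) and the class-defining neurotransmitter genes of their
assigned class (GLUT: Slc17a6; GABA: Slc32a1/Gad1/Gad2; HA: Hdc/Gad1).
A configurable fraction of cells is perturbed into QC failures (low depth,
high mitochondrial fraction, hemoglobin contamination) and flagged in the
emitted truth so quality filters can be scored exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import io_formats
from .errors import SpecError
from .io_formats import GeneAnnotations, annotate_genes

NEURONAL_SIGNATURE = ("Snap25", "Syp", "Tubb3", "Elavl2")
NT_SIGNATURE = ("Slc17a6", "Slc32a1", "Gad1", "Gad2", "Hdc")
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)
HEMOGLOBIN_GENES = ("Hba-a1", "Hba-a2", "Hbb-bs")
RIBO_GENES = ("Rps4x", "Rpl13a", "Rps19", "Rpl7")
CELL_CYCLE_GENES = ("Mki67", "Top2a", "Ccnb1")
IEXCL_GENES = ("Xist", "Fos", "Fosb", "Jun", "Junb", "Jund")

#: genes elevated per neurotransmitter class
NT_CLASS_GENES: dict[str, tuple[str, ...]] = {
    "GLUT": ("Slc17a6",),
    "GABA": ("Slc32a1", "Gad1", "Gad2"),
    "HA": ("Hdc", "Gad1"),
    "NONNEURONAL": (),
}

QC_FAIL_MODES = ("low_depth", "high_mito", "hemoglobin")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated cohort; a pure function of these plus
    ``seed`` fully determines the output."""

    n_cells: int = 1000
    n_genes: int = 3000
    n_clusters: int = 5
    cluster_proportions: tuple[float, ...] | None = None  # None -> uniform
    markers_per_cluster: int = 5
    marker_log2_effect: float = 3.0
    baseline_mean: float = 3.0
    nb_dispersion: float = 0.05  # alpha in var = mu + alpha mu^2; 0 -> Poisson
    depth_batch_factors: tuple[float, ...] = (1.0, 1.5)
    batch_names: tuple[str, ...] = ("V2", "V3")
    sex_names: tuple[str, ...] = ("M", "F")
    neuronal_cluster_ids: tuple[int, ...] = ()
    nt_class_map: Mapping[int, str] = field(default_factory=dict)
    signature_log2_effect: float = 3.0
    qc_fail_fraction: float = 0.0
    qc_fail_modes: tuple[str, ...] = QC_FAIL_MODES
    healthy_mito_fraction: float = 0.05
    fail_mito_fraction: float = 0.25
    hemoglobin_baseline_mean: float = 0.2
    low_depth_scale: float = 0.05
    #: sd (log2 units) of per-cluster multiplicative divergence applied to
    #: background genes, emulating transcriptome-wide differences between
    #: cell types beyond the planted markers; 0 disables it.
    cluster_lognormal_sigma: float = 0.0
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.cluster_proportions is None:
            return np.full(self.n_clusters, 1.0 / self.n_clusters)
        return np.asarray(self.cluster_proportions, dtype=float)

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_clusters <= 0:
            raise SpecError("n_cells, n_genes and n_clusters must be positive")
        p = self.proportions()
        if len(p) != self.n_clusters or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise SpecError("cluster_proportions must be simplex weights of length n_clusters")
        n_special = len(_special_genes())
        if n_special + self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise SpecError(
                "markers_per_cluster x n_clusters exceeds the genes available "
                "after signature/category genes"
            )
        if not set(self.neuronal_cluster_ids) <= set(range(self.n_clusters)):
            raise SpecError("neuronal_cluster_ids outside 0..n_clusters-1")
        if set(self.nt_class_map) != set(self.neuronal_cluster_ids):
            raise SpecError("nt_class_map must be defined exactly on neuronal_cluster_ids")
        if not set(self.nt_class_map.values()) <= {"GLUT", "GABA", "HA"}:
            raise SpecError("nt classes must be GLUT, GABA or HA")
        if not 0 <= self.qc_fail_fraction <= 1:
            raise SpecError("qc_fail_fraction must lie in [0, 1]")
        if not set(self.qc_fail_modes) <= set(QC_FAIL_MODES):
            raise SpecError(f"qc_fail_modes must be a subset of {QC_FAIL_MODES}")
        if self.qc_fail_fraction > 0 and not self.qc_fail_modes:
            raise SpecError("qc_fail_fraction > 0 requires at least one fail mode")
        if len(self.depth_batch_factors) != len(self.batch_names):
            raise SpecError("one depth factor per batch is required")
        if self.nb_dispersion < 0 or self.baseline_mean <= 0 or self.marker_log2_effect < 0:
            raise SpecError("baseline_mean must be positive; dispersion and effect non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted beside every simulated count matrix."""

    true_cluster: np.ndarray
    true_class: np.ndarray  # "neuronal" / "non-neuronal"
    true_nt: np.ndarray  # "GLUT" / "GABA" / "HA" / "NA"
    marker_map: dict[int, list[str]]
    signature_genes: dict[str, list[str]]
    qc_fail: np.ndarray
    qc_mode: np.ndarray  # fail mode per cell, "" for clean cells


def _special_genes() -> list[str]:
    return list(
        NEURONAL_SIGNATURE + NT_SIGNATURE + MITO_GENES + HEMOGLOBIN_GENES
        + RIBO_GENES + CELL_CYCLE_GENES + IEXCL_GENES
    )


def gene_names(spec: SimulationSpec) -> list[str]:
    special = _special_genes()
    n_fill = spec.n_genes - len(special)
    return special + [f"Gene{i:05d}" for i in range(n_fill)]


def marker_map(spec: SimulationSpec) -> dict[int, list[str]]:
    """Planted marker genes per cluster: disjoint blocks of filler genes."""
    names = gene_names(spec)
    start = len(_special_genes())
    m = spec.markers_per_cluster
    return {c: names[start + c * m : start + (c + 1) * m] for c in range(spec.n_clusters)}


def expected_means(spec: SimulationSpec) -> pd.DataFrame:
    """Model mean of each gene in each cluster (before batch depth factors
    and QC perturbations); the closed form the sampler draws from."""
    names = gene_names(spec)
    idx = {g: i for i, g in enumerate(names)}
    K, G = spec.n_clusters, spec.n_genes
    mu = np.full((K, G), spec.baseline_mean)
    for g in HEMOGLOBIN_GENES:
        mu[:, idx[g]] = spec.hemoglobin_baseline_mean
    for c, genes in marker_map(spec).items():
        for g in genes:
            mu[c, idx[g]] = spec.baseline_mean * 2.0 ** spec.marker_log2_effect
    sig = spec.baseline_mean * 2.0 ** spec.signature_log2_effect
    for c in spec.neuronal_cluster_ids:
        for g in NEURONAL_SIGNATURE:
            mu[c, idx[g]] = sig
        for g in NT_CLASS_GENES[spec.nt_class_map[c]]:
            mu[c, idx[g]] = sig
    if spec.cluster_lognormal_sigma > 0:
        # transcriptome-wide divergence: background (non-marker filler) genes
        # drift between clusters; drawn from a seed-derived stream so the
        # model means stay a pure function of the spec
        rng = np.random.default_rng([spec.seed, 7919])
        start = len(_special_genes())
        n_marker = spec.markers_per_cluster * spec.n_clusters
        background = np.arange(start + n_marker, G)
        factors = 2.0 ** (
            spec.cluster_lognormal_sigma * rng.standard_normal((K, len(background)))
        )
        mu[:, background] *= factors
    # mitochondrial means are set so the expected mito fraction is constant
    mito_idx = [idx[g] for g in MITO_GENES]
    other = np.delete(np.arange(G), mito_idx)
    f = spec.healthy_mito_fraction
    mito_total = f / (1.0 - f) * mu[:, other].sum(axis=1)
    mu[:, mito_idx] = (mito_total / len(mito_idx))[:, None]
    return pd.DataFrame(mu, index=pd.RangeIndex(K, name="cluster"), columns=names)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate(spec: SimulationSpec) -> tuple[ad.AnnData, SyntheticTruth]:
    """Draw one cohort; identical spec (including seed) gives identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, G = spec.n_cells, spec.n_genes
    names = gene_names(spec)
    idx = {g: i for i, g in enumerate(names)}

    # cluster assignment by largest-remainder apportionment, then shuffled
    p = spec.proportions()
    counts = np.floor(p * n).astype(int)
    remainder = p * n - counts
    for c in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[c] += 1
    labels = np.repeat(np.arange(spec.n_clusters), counts)
    rng.shuffle(labels)

    # balanced batch x sex groups
    n_batches, n_sexes = len(spec.batch_names), len(spec.sex_names)
    group = np.arange(n) % (n_batches * n_sexes)
    batch_idx = group // n_sexes
    sex_idx = group % n_sexes

    cluster_mu = expected_means(spec).to_numpy()
    mu = cluster_mu[labels] * np.asarray(spec.depth_batch_factors)[batch_idx][:, None]

    # QC failures: exact count, modes cycled in declared order
    n_fail = _round_half_up(spec.qc_fail_fraction * n)
    fail_cells = np.sort(rng.choice(n, size=n_fail, replace=False))
    qc_fail = np.zeros(n, dtype=bool)
    qc_fail[fail_cells] = True
    qc_mode = np.full(n, "", dtype=object)
    modes = list(spec.qc_fail_modes)
    for j, cell in enumerate(fail_cells):
        qc_mode[cell] = modes[j % len(modes)]

    mito_idx = np.array([idx[g] for g in MITO_GENES])
    hgb_idx = np.array([idx[g] for g in HEMOGLOBIN_GENES])
    non_mito = np.delete(np.arange(G), mito_idx)

    low = qc_mode == "low_depth"
    mu[low] *= spec.low_depth_scale
    high = qc_mode == "high_mito"
    if high.any():
        f = spec.fail_mito_fraction
        mito_total = f / (1.0 - f) * mu[np.ix_(high, non_mito)].sum(axis=1)
        mu[np.ix_(high, mito_idx)] = (mito_total / len(mito_idx))[:, None]

    X = _nb_draw(rng, mu, spec.nb_dispersion).astype(np.int64)

    hgb_fail = np.flatnonzero(qc_mode == "hemoglobin")
    for cell in hgb_fail:
        injected = 51 + rng.poisson(100)  # guaranteed past the 50-count gate
        X[cell, hgb_idx] += rng.multinomial(injected, np.full(len(hgb_idx), 1 / len(hgb_idx)))

    neuronal = np.isin(labels, list(spec.neuronal_cluster_ids))
    true_class = np.where(neuronal, "neuronal", "non-neuronal")
    true_nt = np.array([spec.nt_class_map.get(c, "NA") for c in labels], dtype=object)

    obs = pd.DataFrame(
        {
            "sample": [
                f"{spec.batch_names[b]}-{spec.sex_names[s]}" for b, s in zip(batch_idx, sex_idx)
            ],
            "batch": pd.Categorical([spec.batch_names[b] for b in batch_idx]),
            "sex": pd.Categorical([spec.sex_names[s] for s in sex_idx]),
            "true_cluster": labels,
            "true_class": true_class,
            "true_nt": true_nt.astype(str),
            "qc_fail": qc_fail,
            "qc_mode": qc_mode.astype(str),
        },
        index=pd.Index([f"cell{i:06d}" for i in range(n)], name="barcode"),
    )
    var = pd.DataFrame({"gene_id": names}, index=pd.Index(names, name="symbol"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    annotate_genes(adata, GeneAnnotations())

    truth = SyntheticTruth(
        true_cluster=labels,
        true_class=true_class,
        true_nt=true_nt,
        marker_map=marker_map(spec),
        signature_genes={
            "neuronal": list(NEURONAL_SIGNATURE),
            "neurotransmitter": list(NT_SIGNATURE),
        },
        qc_fail=qc_fail,
        qc_mode=qc_mode,
    )
    adata.uns["marker_map"] = {str(c): g for c, g in truth.marker_map.items()}
    adata.uns["signature_genes"] = truth.signature_genes
    return adata, truth


# ---------------------------------------------------------------------------
# presets

N_NEURONAL_CLUSTERS = 20
N_NONNEURONAL_CLUSTERS = 6
_BASE_CELLS = 17000
_NEURONAL_SHARE = 0.55

#: class layout of the 20 neuronal-analog clusters: 13 GLUT, 6 GABA, 1 HA
_NT_LAYOUT = tuple(["GLUT"] * 13 + ["GABA"] * 6 + ["HA"])


def paper_regime_spec(
    scale: float, neuronal_only: bool = False, seed: int = 0
) -> SimulationSpec:
    """Preset emulating the study regime: 20 neuronal-analog + 6 non-neuronal
    clusters across 2 chemistry batches x 2 sexes, with cohort size scaled by
    ``scale``. With ``neuronal_only`` the full (scaled) cell budget is spread
    over the 20 neuronal clusters alone."""
    if scale <= 0:
        raise SpecError("scale must be positive")
    n_cells = max(_round_half_up(_BASE_CELLS * scale), 1)
    if neuronal_only:
        n_clusters = N_NEURONAL_CLUSTERS
        proportions = tuple([1.0 / n_clusters] * n_clusters)
    else:
        n_clusters = N_NEURONAL_CLUSTERS + N_NONNEURONAL_CLUSTERS
        p_neu = _NEURONAL_SHARE / N_NEURONAL_CLUSTERS
        p_non = (1.0 - _NEURONAL_SHARE) / N_NONNEURONAL_CLUSTERS
        proportions = tuple(
            [p_neu] * N_NEURONAL_CLUSTERS + [p_non] * N_NONNEURONAL_CLUSTERS
        )
    neuronal_ids = tuple(range(N_NEURONAL_CLUSTERS))
    nt_map = {c: _NT_LAYOUT[c] for c in neuronal_ids}
    return SimulationSpec(
        n_cells=n_cells,
        n_genes=3000,
        n_clusters=n_clusters,
        cluster_proportions=proportions,
        markers_per_cluster=5,
        marker_log2_effect=3.0,
        neuronal_cluster_ids=neuronal_ids,
        nt_class_map=nt_map,
        qc_fail_fraction=0.08,
        cluster_lognormal_sigma=0.4,
        seed=seed,
    )


def write_simulation(adata: ad.AnnData, truth: SyntheticTruth, out_dir: str) -> None:
    """Write the standard triplet plus truth tables as TSV."""
    io_formats.write_counts_triplet(adata, out_dir)
    os.makedirs(out_dir, exist_ok=True)
    cells = pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "true_cluster": truth.true_cluster,
            "true_class": truth.true_class,
            "true_nt": truth.true_nt,
            "qc_fail": truth.qc_fail.astype(int),
        }
    )
    cells.to_csv(os.path.join(out_dir, "truth_cells.tsv"), sep="\t", index=False)
    rows = [(c, g) for c, genes in truth.marker_map.items() for g in genes]
    pd.DataFrame(rows, columns=["cluster", "marker_gene"]).to_csv(
        os.path.join(out_dir, "truth_markers.tsv"), sep="\t", index=False
    )
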