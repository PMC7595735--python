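import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vph_celltax.io_formats import GeneAnnotations, annotate_genes

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_counts(X, genes=None, annotate=True, **obs_cols) -> ad.AnnData:
    """Build a small annotated count AnnData from a dense array."""
    X = np.asarray(X, dtype=np.int64)
    n, g = X.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(
        {k: list(v) for k, v in obs_cols.items()},
        index=pd.Index([f"c{i}" for i in range(n)], name="barcode"),
    )
    var = pd.DataFrame({"gene_id": genes}, index=pd.Index(genes, name="symbol"))
    adata = ad.AnnData(X=X, obs=obs, var=var)
    if annotate:
        annotate_genes(adata, GeneAnnotations())
    return adata


@pytest.fixture
def counts_factory():
    return make_counts
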