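import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import lungimmune as li


@pytest.fixture(scope="session")
def small_params() -> li.GeneratorParams:
    return li.GeneratorParams(n_genes=1200, n_cells_per_condition=600, seed=11)


@pytest.fixture(scope="session")
def healthy_small(small_params) -> ad.AnnData:
    """One healthy condition at desk scale, reused read-only across tests."""
    return li.simulate_condition("healthy", small_params)


@pytest.fixture(scope="session")
def healthy_processed(healthy_small) -> ad.AnnData:
    return li.preprocess(healthy_small.copy())


def make_adata(X, clusters=None, genes=None, conditions=None) -> ad.AnnData:
    """Tiny dense AnnData helper for hand-computed examples."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    if clusters is not None:
        obs["cluster"] = pd.Categorical([str(c) for c in clusters])
        obs["subtype"] = obs["cluster"]
    if conditions is not None:
        obs["condition"] = list(conditions)
    var = pd.DataFrame(index=genes or [f"g{j}" for j in range(g)])
    var["mito"] = var.index.str.lower().str.startswith("mt-")
    return ad.AnnData(X=sparse.csr_matrix(X), obs=obs, var=var)
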