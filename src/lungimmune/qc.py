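"""Cell/gene quality control, median-count normalization, PCA.

The filtering rules follow the study design: cells are dropped when they
express fewer than 300 genes or carry more than 8% mitochondrial counts
(strictly greater than); genes detected in fewer than 30 cells are dropped,
and ribosomal and sex-associated genes are excluded unconditionally.  Counts
are then scaled so every cell's total equals the median per-cell total,
log-transformed (``ln(1 + x)``) and reduced with PCA (50 components, of
which the first 6 feed the neighbor graph downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA

__all__ = ["QCThresholds", "PCAParams", "filter_cells", "filter_genes",
           "normalize_median", "pca"]

DEFAULT_SEX_GENES = ("Xist", "Ddx3y", "Eif2s3y", "Uty", "Kdm5d")


class EmptyMatrixError(ValueError):
    """Raised when a filter removes everything."""


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 300
    max_mito_fraction: float = 0.08
    min_cells_per_gene: int = 30
    #: prefixes removed unconditionally at the gene filter (ribosomal families)
    excluded_prefixes: tuple[str, ...] = ("Rps", "Rpl")
    excluded_sex_genes: tuple[str, ...] = DEFAULT_SEX_GENES
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_cells_per_gene <= 0:
            raise ValueError("count thresholds must be strictly positive")
        if not 0.0 < self.max_mito_fraction < 1.0:
            raise ValueError("max_mito_fraction must be in (0, 1)")


@dataclass(frozen=True)
class PCAParams:
    n_components: int = 50
    n_components_used_downstream: int = 6

    def __post_init__(self) -> None:
        if not 1 <= self.n_components_used_downstream <= self.n_components:
            raise ValueError("need 1 <= used components <= computed components")


def _mito_mask(adata: ad.AnnData, t: QCThresholds) -> np.ndarray:
    if "mito" in adata.var:
        return adata.var["mito"].to_numpy(dtype=bool)
    return adata.var_names.str.lower().str.startswith(t.mito_prefix.lower()).to_numpy()


def filter_cells(adata: ad.AnnData, t: QCThresholds | None = None
                 ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-complexity and high-mitochondrial cells.

    A cell is removed iff it detects fewer than ``min_genes_per_cell`` genes
    (count > 0) or its mitochondrial count share is strictly greater than
    ``max_mito_fraction``.  Returns the filtered matrix and a report of the
    removed cells with their reason(s).
    """
    t = t or QCThresholds()
    X = sparse.csr_matrix(adata.X)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito = _mito_mask(adata, t)
    mito_counts = np.asarray(X[:, mito].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore"):
        mito_frac = np.divide(mito_counts, totals, out=np.zeros_like(totals),
                              where=totals > 0)
    low = detected < t.min_genes_per_cell
    high = mito_frac > t.max_mito_fraction
    drop = low | high
    reasons = []
    for i in np.flatnonzero(drop):
        r = []
        if low[i]:
            r.append("low_genes")
        if high[i]:
            r.append("high_mito")
        reasons.append(";".join(r))
    report = pd.DataFrame({
        "cell": adata.obs_names[drop],
        "detected_genes": detected[drop],
        "mito_fraction": mito_frac[drop],
        "reason": reasons,
    }).reset_index(drop=True)
    kept = adata[~drop].copy()
    if kept.n_obs == 0:
        raise EmptyMatrixError("cell QC removed every cell")
    return kept, report


def filter_genes(adata: ad.AnnData, t: QCThresholds | None = None
                 ) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove rarely detected genes plus ribosomal/sex-gene families."""
    t = t or QCThresholds()
    X = sparse.csc_matrix(adata.X)
    n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    rare = n_cells < t.min_cells_per_gene
    names = adata.var_names
    family = np.zeros(len(names), dtype=bool)
    for prefix in t.excluded_prefixes:
        family |= np.asarray(names.str.startswith(prefix))
    sex = names.isin(t.excluded_sex_genes)
    drop = rare | family | sex
    reasons = []
    for i in np.flatnonzero(drop):
        r = []
        if rare[i]:
            r.append("rare")
        if family[i]:
            r.append("excluded_family")
        if sex[i]:
            r.append("sex_gene")
        reasons.append(";".join(r))
    report = pd.DataFrame({
        "gene": names[drop],
        "detected_in_cells": n_cells[drop],
        "reason": reasons,
    }).reset_index(drop=True)
    kept = adata[:, ~drop].copy()
    if kept.n_vars == 0:
        raise EmptyMatrixError("gene QC removed every gene")
    return kept, report


def normalize_median(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell to the median total, then ``ln(1 + x)``.

    Raw counts are preserved in ``layers['counts']``; per-cell scale factors
    land in ``obs['scale_factor']``.  The sparsity pattern and the within-cell
    rank order of values are unchanged by construction.
    """
    X = sparse.csr_matrix(adata.X).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts cannot be scaled: {bad[:5]}")
    median = float(np.median(totals))
    factors = median / totals
    out = adata.copy()
    out.layers["counts"] = sparse.csr_matrix(adata.X).copy()
    scaled = sparse.diags(factors) @ X
    scaled.data = np.log1p(scaled.data)
    out.X = scaled.tocsr()
    out.obs["scale_factor"] = factors
    out.uns["normalization"] = {"median_total": median}
    return out


def pca(adata: ad.AnnData, p: PCAParams | None = None) -> ad.AnnData:
    """PCA on centered log-normalized values.

    Scores go to ``obsm['X_pca']``, loadings to ``varm['PCs']`` and the
    explained-variance ratio to ``uns['pca_variance_ratio']``.  Component
    signs are fixed by forcing the largest-magnitude loading of each
    component to be positive, so repeated runs agree exactly.
    """
    p = p or PCAParams()
    if p.n_components > min(adata.n_obs, adata.n_vars):
        raise ValueError(
            f"n_components={p.n_components} exceeds min(cells, genes)="
            f"{min(adata.n_obs, adata.n_vars)}")
    X = adata.X
    dense = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X, dtype=float)
    solver = "full" if min(dense.shape) <= 500 else "randomized"
    model = PCA(n_components=p.n_components, svd_solver=solver, random_state=0)
    scores = model.fit_transform(dense)
    components = model.components_
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(components[np.arange(len(components)),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    components = components * flip[:, None]
    out = adata.copy()
    out.obsm["X_pca"] = scores
    out.varm["PCs"] = components.T
    out.uns["pca_variance_ratio"] = model.explained_variance_ratio_
    out.uns["pca_params"] = {"n_components": p.n_components,
                             "n_components_used_downstream": p.n_components_used_downstream}
    return out
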