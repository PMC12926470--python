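"""End-to-end convenience wrappers tying the stages together.

These functions run the canonical stage order — QC, normalization, PCA,
neighbor graph, Leiden, signature annotation — on one dataset and are what
the CLI, the acceptance script and the recovery tests call.
"""

from __future__ import annotations

from dataclasses import replace

import anndata as ad
import pandas as pd

from . import profiles
from .clustering import (ClusteringParams, SignatureSet, annotate_clusters,
                         leiden_cluster, neighbors_and_umap)
from .qc import PCAParams, QCThresholds, filter_cells, filter_genes, normalize_median, pca
from .synthetic import GeneratorParams, generate_dataset

__all__ = ["preprocess", "cluster_and_annotate", "run_condition_pipeline",
           "annotated_fractions", "simulate_condition", "simulate_experiment"]


def preprocess(adata: ad.AnnData, qc_thresholds: QCThresholds | None = None,
               pca_params: PCAParams | None = None) -> ad.AnnData:
    """Cell filter -> gene filter -> median normalization -> PCA."""
    adata, _ = filter_cells(adata, qc_thresholds)
    adata, _ = filter_genes(adata, qc_thresholds)
    adata = normalize_median(adata)
    pca_params = pca_params or PCAParams()
    max_comp = min(adata.n_obs, adata.n_vars)
    if pca_params.n_components > max_comp:
        pca_params = replace(pca_params, n_components=max_comp,
                             n_components_used_downstream=min(
                                 pca_params.n_components_used_downstream, max_comp))
    return pca(adata, pca_params)


def cluster_and_annotate(adata: ad.AnnData, signatures: SignatureSet,
                         params: ClusteringParams | None = None,
                         *, compute_umap: bool = False,
                         cluster_key: str = "cluster",
                         key_added: str = "cell_type") -> ad.AnnData:
    """Neighbors (+ optional UMAP), Leiden, signature annotation."""
    adata = neighbors_and_umap(adata, params, compute_umap=compute_umap)
    adata = leiden_cluster(adata, params, key_added=cluster_key)
    annotate_clusters(adata, signatures, cluster_key, key_added=key_added)
    return adata


def run_condition_pipeline(adata: ad.AnnData, signatures: SignatureSet,
                           qc_thresholds: QCThresholds | None = None,
                           pca_params: PCAParams | None = None,
                           clustering_params: ClusteringParams | None = None,
                           *, compute_umap: bool = False) -> ad.AnnData:
    """Full QC -> clustering -> annotation for one count matrix."""
    adata = preprocess(adata, qc_thresholds, pca_params)
    return cluster_and_annotate(adata, signatures, clustering_params,
                                compute_umap=compute_umap)


def annotated_fractions(adata: ad.AnnData, key: str = "cell_type") -> pd.Series:
    """Fraction of cells per annotated type, descending label order fixed."""
    counts = adata.obs[key].astype(str).value_counts()
    return (counts / counts.sum()).sort_index()


def simulate_condition(condition: str, params: GeneratorParams,
                       *, compartment: str | None = None) -> ad.AnnData:
    """Generate one condition from the packaged profiles and programs."""
    if compartment is None:
        profile = profiles.full_profile(condition)
        programs = profiles.default_programs()
    else:
        profile = profiles.compartment_profile(compartment, condition)
        programs = profiles.default_programs(compartment)
    return generate_dataset(profile, programs, params)


def simulate_experiment(params: GeneratorParams,
                        conditions: tuple[str, ...] = profiles.CONDITIONS
                        ) -> ad.AnnData:
    """Generate the full three-condition design in one matrix."""
    profs = [profiles.full_profile(c) for c in conditions]
    return generate_dataset(profs, profiles.default_programs(), params)
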