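"""Neighbor graph, UMAP, Leiden clustering, marker ranking and annotation.

The embedding/clustering stack mirrors the study pipeline: a k-nearest-
neighbor graph on the first 6 principal components, UMAP (spread 2.0,
min_dist 0.3) for visualization, and Leiden community detection at
resolution 0.5.  Marker genes are ranked per cluster one-vs-rest with a
Welch t-test and Benjamini-Hochberg correction, then filtered by three
rules: at least 25% of in-cluster cells expressing the gene, log2 fold
change >= 0.5 against the aggregate of all other clusters, and at most 80%
of cells outside the cluster expressing it.  Cluster annotation replaces
the study's manual curation with a reproducible signature score: the
cluster-mean expression of each signature gene is z-scored across clusters
and averaged, and the cluster is assigned to the argmax signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .qc import PCAParams, pca

__all__ = [
    "ClusteringParams", "MarkerFilter", "SignatureSet",
    "neighbors_and_umap", "leiden_cluster", "rank_markers", "filter_markers",
    "condition_markers", "annotate_clusters", "subcluster",
]


@dataclass(frozen=True)
class ClusteringParams:
    n_pcs: int = 6
    umap_spread: float = 2.0
    umap_min_dist: float = 0.3
    leiden_resolution: float = 0.5
    n_neighbors: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leiden_resolution <= 0:
            raise ValueError("leiden_resolution must be > 0")
        if self.n_pcs < 1 or self.n_neighbors < 1:
            raise ValueError("n_pcs and n_neighbors must be >= 1")


@dataclass(frozen=True)
class MarkerFilter:
    """The three marker-retention rules (all boundaries inclusive)."""

    min_in_fraction: float = 0.25
    min_fold_change: float = 0.5  # log2 scale
    max_out_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_in_fraction", "max_out_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SignatureSet:
    """Named collection of cell-type gene signatures."""

    name: str
    signatures: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.signatures:
            raise ValueError("signature set is empty")
        for label, genes in self.signatures.items():
            if not genes:
                raise ValueError(f"signature {label!r} has no genes")
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature {label!r} has duplicate genes")


def neighbors_and_umap(adata: ad.AnnData, p: ClusteringParams | None = None,
                       *, compute_umap: bool = True) -> ad.AnnData:
    """kNN graph on the leading PCs, plus (optionally) the 2-D UMAP.

    The UMAP embedding is only used for visualization; composition and
    marker statistics never depend on it, so pipeline callers may skip it.
    """
    p = p or ClusteringParams()
    if adata.n_obs < p.n_neighbors + 1:
        raise ValueError(
            f"{adata.n_obs} cells is fewer than n_neighbors+1={p.n_neighbors + 1}")
    if "X_pca" not in adata.obsm:
        raise ValueError("run pca() first: obsm['X_pca'] missing")
    if adata.obsm["X_pca"].shape[1] < p.n_pcs:
        raise ValueError("fewer PCA components available than n_pcs")
    out = adata.copy()
    sc.pp.neighbors(out, n_neighbors=p.n_neighbors, n_pcs=p.n_pcs,
                    random_state=p.seed)
    if compute_umap:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.tl.umap(out, spread=p.umap_spread, min_dist=p.umap_min_dist,
                       random_state=p.seed)
    return out


def leiden_cluster(adata: ad.AnnData, p: ClusteringParams | None = None,
                   *, key_added: str = "cluster") -> ad.AnnData:
    """Leiden partition of the neighbor graph.

    Labels are relabeled contiguously from 0 in order of decreasing cluster
    size (ties by smallest member index) so runs are comparable.
    """
    p = p or ClusteringParams()
    if "connectivities" not in adata.obsp:
        raise ValueError("run neighbors_and_umap() first: graph missing")
    conn = sparse.coo_matrix(sparse.triu(adata.obsp["connectivities"]))
    g = igraph.Graph(n=adata.n_obs,
                     edges=list(zip(conn.row.tolist(), conn.col.tolist())),
                     edge_attrs={"weight": conn.data.tolist()})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=p.leiden_resolution,
        seed=p.seed, n_iterations=2)
    raw = np.asarray(part.membership)
    order = sorted(np.unique(raw),
                   key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])))
    remap = {c: i for i, c in enumerate(order)}
    out = adata.copy()
    labels = np.array([remap[c] for c in raw])
    out.obs[key_added] = pd.Categorical([str(c) for c in labels],
                                        categories=[str(i) for i in range(len(order))])
    return out


def _group_stats(X: sparse.csr_matrix, mask: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean, sample variance, expressing fraction, de-logged mean per gene."""
    sub = X[mask]
    n = sub.shape[0]
    s1 = np.asarray(sub.sum(axis=0)).ravel()
    s2 = np.asarray(sub.multiply(sub).sum(axis=0)).ravel()
    mean = s1 / n
    var = (s2 - n * mean**2) / max(n - 1, 1)
    var = np.maximum(var, 0.0)
    frac = np.asarray((sub > 0).sum(axis=0)).ravel() / n
    expm = np.asarray(sub.copy().expm1().sum(axis=0)).ravel() / n
    return mean, var, frac, expm


def rank_markers(adata: ad.AnnData, cluster_key: str = "cluster",
                 *, layer: str | None = None) -> pd.DataFrame:
    """One-vs-rest Welch t marker ranking with BH correction per cluster.

    Expects log-normalized values in ``X``.  Returns a long table with one
    row per (cluster, gene): t statistic, two-sided raw and BH-adjusted p
    (family = the cluster's gene list), log2 fold change of de-logged group
    means, and in/out expressing fractions, sorted by descending t within
    cluster.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"obs[{cluster_key!r}] missing")
    X = sparse.csr_matrix(adata.layers[layer] if layer else adata.X).astype(float)
    labels = adata.obs[cluster_key].astype(str).to_numpy()
    frames = []
    for cluster in sorted(pd.unique(labels)):
        mask = labels == cluster
        n1, n0 = int(mask.sum()), int((~mask).sum())
        if n1 < 2 or n0 < 2:
            warnings.warn(f"cluster {cluster!r} skipped: needs >=2 cells in "
                          "both group and rest")
            continue
        m1, v1, f1, e1 = _group_stats(X, mask)
        m0, v0, f0, e0 = _group_stats(X, ~mask)
        se2 = v1 / n1 + v0 / n0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se2 > 0, (m1 - m0) / np.sqrt(se2), 0.0)
            df = np.where(se2 > 0,
                          se2**2 / ((v1 / n1)**2 / max(n1 - 1, 1)
                                    + (v0 / n0)**2 / max(n0 - 1, 1) + 1e-300),
                          1.0)
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
        pvals = np.clip(pvals, 0.0, 1.0)
        adj = multipletests(pvals, method="fdr_bh")[1]
        log2fc = np.log2((e1 + 1e-9) / (e0 + 1e-9))
        frame = pd.DataFrame({
            "cluster": cluster,
            "gene": adata.var_names,
            "t": t,
            "pval": pvals,
            "pval_adj": adj,
            "log2fc": log2fc,
            "frac_in": f1,
            "frac_out": f0,
        })
        frame = frame.sort_values(["t", "gene"], ascending=[False, True],
                                  kind="stable")
        frames.append(frame)
    if not frames:
        raise ValueError("no cluster had enough cells to rank markers")
    return pd.concat(frames, ignore_index=True)


def filter_markers(table: pd.DataFrame, f: MarkerFilter | None = None
                   ) -> pd.DataFrame:
    """Apply the three marker rules; returns the retained rows with flags."""
    f = f or MarkerFilter()
    out = table.copy()
    out["pass_in_fraction"] = out["frac_in"] >= f.min_in_fraction
    out["pass_fold_change"] = out["log2fc"] >= f.min_fold_change
    out["pass_out_fraction"] = out["frac_out"] <= f.max_out_fraction
    out["selected"] = (out["pass_in_fraction"] & out["pass_fold_change"]
                       & out["pass_out_fraction"])
    return out[out["selected"]].reset_index(drop=True)


def condition_markers(adata: ad.AnnData, cluster_key: str = "cluster",
                      condition_key: str = "condition",
                      f: MarkerFilter | None = None) -> pd.DataFrame:
    """Marker ranking and filtering within each condition stratum."""
    frames = []
    for condition in sorted(pd.unique(adata.obs[condition_key].astype(str))):
        sub = adata[adata.obs[condition_key].astype(str) == condition]
        counts = sub.obs[cluster_key].astype(str).value_counts()
        if (counts >= 2).sum() < 2:
            warnings.warn(f"condition {condition!r} skipped: fewer than two "
                          "clusters with >=2 cells")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = rank_markers(sub.copy(), cluster_key)
        table = filter_markers(table, f)
        table.insert(1, "condition", condition)
        frames.append(table)
    if not frames:
        return pd.DataFrame(columns=["cluster", "condition", "gene"])
    return pd.concat(frames, ignore_index=True)


def annotate_clusters(adata: ad.AnnData, signatures: SignatureSet,
                      cluster_key: str = "cluster",
                      *, key_added: str = "cell_type",
                      sd_floor: float = 0.05
                      ) -> tuple[dict[str, str], pd.DataFrame]:
    """Assign each cluster to the best-scoring signature.

    score(cluster, type) = mean over the signature's present genes of the
    cluster-mean expression z-scored across clusters (population sd).  The
    sd is floored at ``sd_floor`` (log-expression units) so genes that are
    flat up to sampling noise score near zero instead of being inflated to
    full z-scores; genuinely marked genes move cluster means by an order of
    magnitude more than the floor.  Ties break lexicographically on the
    type label.  Returns the cluster->type map and the full score matrix;
    the per-cell assignment is written to ``obs[key_added]``.
    """
    labels = adata.obs[cluster_key].astype(str).to_numpy()
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 1:
        raise ValueError("no clusters to annotate")
    X = sparse.csr_matrix(adata.X).astype(float)
    means = np.vstack([
        np.asarray(X[labels == c].mean(axis=0)).ravel() for c in clusters])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)  # population sd across clusters
    z = (means - mu) / np.maximum(sd, sd_floor)
    zframe = pd.DataFrame(z, index=clusters, columns=adata.var_names)
    scores = {}
    for label in sorted(signatures.signatures):
        present = [g for g in signatures.signatures[label] if g in adata.var_names]
        if not present:
            warnings.warn(f"signature {label!r} has no genes in the matrix; excluded")
            continue
        scores[label] = zframe[present].mean(axis=1)
    if not scores:
        raise ValueError("no signature had any gene present in the matrix")
    score_matrix = pd.DataFrame(scores)  # clusters x types, columns sorted
    assignment = {}
    for cluster in clusters:
        row = score_matrix.loc[cluster]
        best = row[row == row.max()].index.min()  # lexicographic tie-break
        assignment[cluster] = best
    adata.obs[key_added] = pd.Series(labels, index=adata.obs_names).map(assignment)
    return assignment, score_matrix


def subcluster(adata: ad.AnnData, compartment: str,
               p: ClusteringParams | None = None,
               pca_params: PCAParams | None = None,
               *, compartment_key: str = "cell_type",
               compute_umap: bool = False) -> ad.AnnData:
    """Recluster the cells of one annotated compartment.

    PCA, neighbors (and optionally UMAP) and Leiden are recomputed on the
    subset alone; all downstream marker/enrichment/interaction/proportion
    operations apply to the result unchanged.
    """
    p = p or ClusteringParams()
    if compartment_key not in adata.obs:
        raise ValueError(f"obs[{compartment_key!r}] missing; annotate first")
    mask = adata.obs[compartment_key].astype(str) == compartment
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"compartment {compartment!r} not found")
    if n < p.n_neighbors + 1:
        raise ValueError(
            f"compartment {compartment!r} has {n} cells; need at least "
            f"{p.n_neighbors + 1}")
    sub = adata[mask].copy()
    pca_params = pca_params or PCAParams(
        n_components=min(50, sub.n_obs - 1, sub.n_vars - 1))
    sub = pca(sub, pca_params)
    sub = neighbors_and_umap(sub, p, compute_umap=compute_umap)
    sub = leiden_cluster(sub, p, key_added="subcluster")
    return sub
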