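"""Graph/UMAP/Leiden, marker statistics and signature annotation."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

import lungimmune as li
from lungimmune import profiles
from lungimmune.synthetic import GeneratorParams

from conftest import make_adata


def _blob_adata(n=240, centers=4, sep=30.0, seed=0):
    X, y = make_blobs(n_samples=n, centers=centers, n_features=6,
                      cluster_std=1.0, center_box=(-sep, sep), random_state=seed)
    adata = make_adata(np.abs(X))
    adata.obsm["X_pca"] = X
    adata.obs["truth"] = y.astype(str)
    return adata


def test_umap_seed_determinism_and_shape():
    adata = _blob_adata()
    p = li.ClusteringParams(n_neighbors=10, seed=3)
    a = li.neighbors_and_umap(adata, p)
    b = li.neighbors_and_umap(adata, p)
    assert a.obsm["X_umap"].shape == (adata.n_obs, 2)
    np.testing.assert_allclose(a.obsm["X_umap"], b.obsm["X_umap"])


def test_neighbors_stay_within_separated_clouds():
    adata = _blob_adata(centers=2, sep=60.0)
    out = li.neighbors_and_umap(adata, li.ClusteringParams(n_neighbors=10),
                                compute_umap=False)
    conn = out.obsp["connectivities"].tocoo()
    truth = out.obs["truth"].to_numpy()
    same = (truth[conn.row] == truth[conn.col]).mean()
    assert same > 0.99


def test_neighbors_requires_enough_cells():
    adata = _blob_adata(n=8)
    with pytest.raises(ValueError, match="cells"):
        li.neighbors_and_umap(adata, li.ClusteringParams(n_neighbors=15))


def test_leiden_recovers_separated_blobs():
    adata = _blob_adata(centers=4, sep=60.0)
    p = li.ClusteringParams(n_neighbors=10, seed=1)
    out = li.leiden_cluster(li.neighbors_and_umap(adata, p, compute_umap=False), p)
    ari = adjusted_rand_score(out.obs["truth"], out.obs["cluster"])
    assert ari >= 0.8
    # labels contiguous from 0, every cell labelled
    labels = out.obs["cluster"].astype(int)
    assert labels.min() == 0
    assert set(labels) == set(range(labels.max() + 1))


def test_leiden_seed_determinism():
    adata = _blob_adata()
    p = li.ClusteringParams(n_neighbors=10, seed=7)
    g = li.neighbors_and_umap(adata, p, compute_umap=False)
    a = li.leiden_cluster(g, p)
    b = li.leiden_cluster(g, p)
    assert (a.obs["cluster"] == b.obs["cluster"]).all()


def test_leiden_two_cliques_two_clusters():
    # two disconnected complete graphs carry no finer structure to split
    n = 40
    conn = np.zeros((n, n))
    conn[:20, :20] = 1.0
    conn[20:, 20:] = 1.0
    np.fill_diagonal(conn, 0.0)
    adata = make_adata(np.ones((n, 3)))
    adata.obsp["connectivities"] = sparse.csr_matrix(conn)
    out = li.leiden_cluster(adata, li.ClusteringParams(seed=0))
    labels = out.obs["cluster"].to_numpy()
    assert out.obs["cluster"].nunique() == 2
    assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1


def test_welch_t_closed_form():
    # group {1,2,3} vs rest {0,1,2}: mean diff 1, s^2=1 each -> t = 1/sqrt(2/3)
    X = np.array([[1.0], [2.0], [3.0], [0.0], [1.0], [2.0]])
    adata = make_adata(X, clusters=[1, 1, 1, 0, 0, 0])
    table = li.rank_markers(adata, "cluster")
    t_val = table.loc[table["cluster"] == "1", "t"].item()
    np.testing.assert_allclose(t_val, 1.0 / np.sqrt(2.0 / 3.0), atol=1e-6)


def test_bh_step_up_hand_example():
    # [0.01, 0.02, 0.03, 0.04] with m=4 -> all adjusted to 0.04
    from statsmodels.stats.multitest import multipletests
    adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_identical_gene_gives_zero_t():
    rng = np.random.default_rng(3)
    flat = np.tile([[1.0, 2.0]], (8, 1))
    marker = np.r_[np.full(4, 5.0), np.zeros(4)][:, None]
    adata = make_adata(np.hstack([flat, marker]), clusters=[1] * 4 + [0] * 4)
    table = li.rank_markers(adata, "cluster")
    flat_rows = table[table["gene"].isin(["g0", "g1"])]
    assert (flat_rows["t"] == 0).all()
    assert (flat_rows["pval"] == 1.0).all()


def test_bh_monotone_and_bounded(healthy_processed):
    sub = healthy_processed[:200].copy()
    sub.obs["cluster"] = ["a" if c == "B" else "b"
                          for c in sub.obs["compartment"]]
    table = li.rank_markers(sub, "cluster")
    for _, grp in table.groupby("cluster"):
        g = grp.sort_values("pval", kind="stable")
        assert (np.diff(g["pval_adj"]) >= -1e-12).all()
        assert g["pval_adj"].between(0, 1).all()


def test_marker_filter_boundaries_inclusive():
    base = pd.DataFrame({
        "cluster": "0", "gene": ["a", "b", "c", "d"],
        "t": 1.0, "pval": 0.01, "pval_adj": 0.01,
        "log2fc": [0.5, 0.5, 0.49, 0.5],
        "frac_in": [0.25, 0.24, 0.25, 0.25],
        "frac_out": [0.80, 0.80, 0.80, 0.81],
    })
    kept = li.filter_markers(base)
    assert list(kept["gene"]) == ["a"]


def test_marker_filter_idempotent_subset(healthy_processed):
    sub = healthy_processed[:300].copy()
    sub.obs["cluster"] = sub.obs["compartment"].astype(str)
    table = li.rank_markers(sub, "cluster")
    once = li.filter_markers(table)
    twice = li.filter_markers(once)
    assert len(once) <= len(table)
    pd.testing.assert_frame_equal(
        once.drop(columns=[c for c in once if c.startswith("pass") or c == "selected"]),
        twice.drop(columns=[c for c in twice if c.startswith("pass") or c == "selected"]))


def test_condition_specific_marker_detected():
    # a gene boosted only in (resting_B, LLC1) shows up there and not healthy
    from lungimmune.synthetic import ProgramSpec, generate_dataset
    profile_h = profiles.compartment_profile("B", "healthy")
    profile_l = profiles.compartment_profile("B", "LLC1")
    progs = profiles.default_programs("B") + [
        ProgramSpec("resting_B", "LLC1", ["CondGeneX"], 2.5)]
    params = GeneratorParams(n_genes=1200, n_cells_per_condition=500, seed=9)
    adata = generate_dataset([profile_h, profile_l], progs, params)
    norm = li.normalize_median(adata)
    norm.obs["cluster"] = norm.obs["subtype"].astype(str)
    table = li.condition_markers(norm, "cluster", "condition")
    hits = table[table["gene"] == "CondGeneX"]
    assert (("resting_B", "LLC1") in
            set(zip(hits["cluster"], hits["condition"])))
    assert not (hits["condition"] == "healthy").any()


def test_single_condition_equals_plain_ranking(healthy_processed):
    sub = healthy_processed[:300].copy()
    sub.obs["cluster"] = sub.obs["compartment"].astype(str)
    plain = li.filter_markers(li.rank_markers(sub, "cluster"))
    strat = li.condition_markers(sub, "cluster", "condition")
    pd.testing.assert_frame_equal(
        plain.reset_index(drop=True),
        strat.drop(columns="condition").reset_index(drop=True))


def test_annotation_recovers_disjoint_planted_markers(healthy_processed):
    sub = healthy_processed.copy()
    sub.obs["cluster"] = sub.obs["compartment"].astype(str)
    sig = li.SignatureSet("compartments", profiles.compartment_signatures())
    assignment, scores = li.annotate_clusters(sub, sig, "cluster")
    assert assignment == {c: c for c in assignment}


def test_annotation_degenerate_ties_lexicographic():
    X = np.ones((6, 4))
    adata = make_adata(X, clusters=[0, 0, 1, 1, 2, 2])
    sig = li.SignatureSet("s", {"beta": ["g0", "g1"], "alpha": ["g2", "g3"]})
    assignment, scores = li.annotate_clusters(adata, sig, "cluster")
    assert (scores.to_numpy() == 0).all()
    assert set(assignment.values()) == {"alpha"}


def test_annotation_single_boosted_gene():
    X = np.ones((6, 3))
    X[0:2, 0] = 9.0
    adata = make_adata(X, clusters=[0, 0, 1, 1, 2, 2])
    sig = li.SignatureSet("s", {"hot": ["g0"], "cold": ["g1"]})
    assignment, _ = li.annotate_clusters(adata, sig, "cluster")
    assert assignment["0"] == "hot"


def test_annotation_permutation_equivariant(healthy_processed):
    sub = healthy_processed[:400].copy()
    sub.obs["cluster"] = sub.obs["compartment"].astype(str)
    sig = li.SignatureSet("compartments", profiles.compartment_signatures())
    a, _ = li.annotate_clusters(sub.copy(), sig, "cluster")
    relabel = {"B": "w", "T": "x", "NK": "y", "macrophage": "z"}
    sub2 = sub.copy()
    sub2.obs["cluster"] = sub.obs["cluster"].map(relabel)
    b, _ = li.annotate_clusters(sub2, sig, "cluster")
    assert b == {relabel[k]: v for k, v in a.items()}


def test_annotation_warns_on_absent_signature(healthy_processed):
    sub = healthy_processed[:100].copy()
    sub.obs["cluster"] = sub.obs["compartment"].astype(str)
    sig = li.SignatureSet("s", {"B": profiles.COMPARTMENT_MARKERS["B"],
                                "ghost": ["NotAGene1", "NotAGene2"]})
    with pytest.warns(UserWarning, match="ghost"):
        li.annotate_clusters(sub, sig, "cluster")


def test_subcluster_recovers_balanced_subtypes():
    # balanced 5-subtype B compartment: annotated labels match truth
    fractions = {s: 0.2 for s in
                 ("mature_B", "resting_B", "plasma_cell", "pre_Bcr", "late_proB")}
    profile = li.CompositionProfile("healthy", fractions,
                                    {s: "B" for s in fractions})
    adata = li.generate_dataset(profile, profiles.default_programs("B"),
                                GeneratorParams(n_genes=1200,
                                                n_cells_per_condition=1000, seed=21))
    sig = li.SignatureSet("B", profiles.subtype_signatures("B"))
    res = li.run_condition_pipeline(adata, sig)
    ari = adjusted_rand_score(res.obs["subtype"], res.obs["cell_type"])
    assert ari >= 0.8


def test_subcluster_partitions_compartment(healthy_processed):
    adata = healthy_processed.copy()
    adata.obs["cell_type"] = adata.obs["compartment"].astype(str)
    p = li.ClusteringParams(n_neighbors=10, seed=0)
    sub = li.subcluster(adata, "NK", p)
    assert sub.n_obs == (adata.obs["cell_type"] == "NK").sum()
    assert sub.obs["subcluster"].notna().all()


def test_subcluster_too_small_rejected(healthy_processed):
    adata = healthy_processed[:30].copy()
    adata.obs["cell_type"] = "tiny"
    with pytest.raises(ValueError, match="cells"):
        li.subcluster(adata, "tiny", li.ClusteringParams(n_neighbors=40))
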