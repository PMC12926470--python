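"""Interaction score algebra, validity rules, quantile-rank differentials."""

import numpy as np
import pandas as pd
import pytest

import lungimmune as li
from lungimmune import profiles
from lungimmune.interaction import LRDatabase
from lungimmune.synthetic import GeneratorParams

from conftest import make_adata


def _two_cluster_toy():
    # two equal-size clusters; ligand means (2,0) f=(1,0); receptor means (1,3)
    X = np.array([
        # lig rec
        [2.0, 1.0],
        [2.0, 1.0],
        [0.0, 3.0],
        [0.0, 3.0],
    ])
    return make_adata(X, clusters=["c1", "c1", "c2", "c2"], genes=["Lig", "Rec"])


def _db(pairs):
    return LRDatabase(pairs=tuple(
        (tuple(l.split("_")), tuple(r.split("_"))) for l, r in pairs))


def test_component_score_flat_gene_zero():
    X = np.full((6, 1), 2.0)
    adata = make_adata(X, clusters=[0, 0, 1, 1, 2, 2], genes=["g"])
    s = li.component_score(adata, "cluster", "g")
    np.testing.assert_allclose(s.to_numpy(), 0.0)


def test_component_score_hand_example():
    s = li.component_score(_two_cluster_toy(), "cluster")
    # ligand: z = (+1, -1), w = 0.5, f = (1, 0) -> s = (+0.5, 0)
    np.testing.assert_allclose(s["Lig"].to_numpy(), [0.5, 0.0])
    # receptor: z = (-1, +1), w = 0.5, f = (1, 1) -> s = (-0.5, +0.5)
    np.testing.assert_allclose(s["Rec"].to_numpy(), [-0.5, 0.5])


def test_component_score_scale_invariance_of_z():
    adata = _two_cluster_toy()
    tripled = adata.copy()
    tripled.X = adata.X * 3.0
    s1 = li.component_score(adata, "cluster")
    s2 = li.component_score(tripled, "cluster")
    # expressing fractions unchanged, z unchanged -> scores equal
    pd.testing.assert_frame_equal(s1, s2)


def test_component_score_single_cluster_rejected():
    X = np.ones((4, 2))
    adata = make_adata(X, clusters=[0, 0, 0, 0])
    with pytest.raises(ValueError, match="two clusters"):
        li.component_score(adata, "cluster")


def test_interaction_score_hand_example():
    table, agg = li.score_interactions(_two_cluster_toy(), _db([("Lig", "Rec")]))
    row = table[(table["source"] == "c1") & (table["target"] == "c2")]
    assert row["valid"].item()
    assert row["score"].item() == pytest.approx(1.0)  # 0.5 + 0.5


def test_zero_fraction_unit_invalid():
    table, _ = li.score_interactions(_two_cluster_toy(), _db([("Lig", "Rec")]))
    # ligand not expressed in c2 -> any pairing with source c2 invalid
    src2 = table[table["source"] == "c2"]
    assert (~src2["valid"]).all()
    assert src2["score"].isna().all()


def test_aggregate_equals_row_sum():
    rng = np.random.default_rng(4)
    X = rng.poisson(1.0, size=(60, 8)).astype(float)
    genes = [f"G{i}" for i in range(8)]
    adata = make_adata(X, clusters=rng.integers(0, 3, 60), genes=genes)
    db = _db([("G0", "G1"), ("G2", "G3"), ("G4", "G5_G6")])
    table, agg = li.score_interactions(adata, db)
    for row in agg.itertuples():
        expected = table[(table["source"] == row.source)
                         & (table["target"] == row.target)
                         & table["valid"]]["score"].sum()
        assert row.total_score == pytest.approx(expected)


def test_complex_uses_limiting_subunit():
    X = np.array([
        [5.0, 1.0, 0.0],
        [5.0, 1.0, 0.0],
        [0.0, 0.0, 2.0],
        [0.0, 0.0, 2.0],
    ])
    adata = make_adata(X, clusters=["a", "a", "b", "b"], genes=["L", "R1", "R2"])
    s = li.component_score(adata, "cluster")
    table, _ = li.score_interactions(adata, _db([("L", "R1_R2")]))
    row = table[(table["source"] == "a") & (table["target"] == "a")]
    # receptor unit score in 'a' = min(s(R1,a), s(R2,a)); R2 absent in 'a'
    expected_unit = min(s["R1"]["a"], s["R2"]["a"])
    assert row["s_receptor"].item() == pytest.approx(expected_unit)
    # fraction = min subunit fraction = 0 -> invalid in cluster a
    assert not row["valid"].item()


def test_missing_gene_marks_untestable():
    with pytest.warns(UserWarning, match="untestable"):
        table, agg = li.score_interactions(_two_cluster_toy(),
                                           _db([("Lig", "Rec"), ("Nope", "Rec")]))
    bad = table[table["pair"] == "Nope->Rec"]
    assert bad["untestable"].all()
    assert not bad["valid"].any()


def test_z_sums_to_zero_over_clusters():
    rng = np.random.default_rng(5)
    X = rng.poisson(2.0, size=(90, 6)).astype(float)
    adata = make_adata(X, clusters=rng.integers(0, 3, 90))
    clusters, = [sorted(adata.obs["cluster"].unique())]
    means = pd.DataFrame(
        {c: np.asarray(adata.X[(adata.obs["cluster"] == c).to_numpy()].mean(axis=0)).ravel()
         for c in clusters}).T
    z = (means - means.mean(axis=0)) / means.std(axis=0, ddof=0)
    np.testing.assert_allclose(z.sum(axis=0), 0.0, atol=1e-9)


def test_planted_pair_attains_max_score_and_rank_one():
    params = GeneratorParams(n_genes=1200, n_cells_per_condition=800, seed=13)
    adata = li.simulate_condition("healthy", params)
    adata = li.plant_lr_signal(adata, "Tgfb1", "Tgfbr1", "resting_B", "Cd4_T",
                               boost=3.0, seed=13)
    norm = li.normalize_median(adata)
    norm.obs["cluster"] = norm.obs["subtype"].astype(str)
    db = _db([("Tgfb1", "Tgfbr1")])
    table, _ = li.score_interactions(norm, db)
    valid = table[table["valid"]]
    best = valid.loc[valid["score"].idxmax()]
    assert (best["source"], best["target"]) == ("resting_B", "Cd4_T")
    # the planted interaction carries the top quantile rank
    from lungimmune.interaction import _quantile_ranks
    ranks = _quantile_ranks(table)
    assert ranks.loc[valid["score"].idxmax()] == pytest.approx(1.0)


def test_quantile_ranks_monotone():
    rng = np.random.default_rng(6)
    X = rng.poisson(1.5, size=(80, 10)).astype(float)
    adata = make_adata(X, clusters=rng.integers(0, 4, 80))
    db = _db([(f"g{i}", f"g{i+5}") for i in range(5)])
    table, _ = li.score_interactions(adata, db)
    from lungimmune.interaction import _quantile_ranks
    valid = table[table["valid"]]
    ranks = _quantile_ranks(table)
    order = valid["score"].sort_values(kind="stable").index
    assert (ranks.loc[order].diff().dropna() >= -1e-12).all()
    assert ranks.max() == pytest.approx(1.0)


def test_top_connections_caps_and_recovers_planted():
    table, _ = li.score_interactions(_two_cluster_toy(), _db([("Lig", "Rec")]))
    top = li.top_connections(table, k=1)
    lig_rows = top[(top["role"] == "ligand") & (top["cluster"] == "c1")]
    assert list(lig_rows["unit"]) == ["Lig"]
    assert (top.groupby(["cluster", "role"]).size() <= 1).all()


def test_differential_identity_and_antisymmetry():
    rng = np.random.default_rng(7)
    X = rng.poisson(1.5, size=(100, 8)).astype(float)
    adata = make_adata(X, clusters=rng.integers(0, 3, 100))
    db = _db([("g0", "g1"), ("g2", "g3"), ("g4", "g5")])
    table, _ = li.score_interactions(adata, db)
    same = li.differential_interactions(table, table)
    np.testing.assert_allclose(same.shared["delta_rank"], 0.0)
    # antisymmetry against a perturbed second table
    X2 = rng.poisson(1.5, size=(100, 8)).astype(float)
    adata2 = make_adata(X2, clusters=rng.integers(0, 3, 100))
    table2, _ = li.score_interactions(adata2, db)
    ab = li.differential_interactions(table, table2)
    ba = li.differential_interactions(table2, table)
    merged = ab.shared.merge(ba.shared, on=["pair", "source", "target"])
    np.testing.assert_allclose(merged["delta_rank_x"],
                               -merged["delta_rank_y"], atol=1e-12)


def test_differential_hand_ranks():
    # scores A {1,2,3}, B {3,2,1} for three pairings -> deltas -2/3, 0, +2/3
    def table_for(scores):
        return pd.DataFrame({
            "pair": ["p", "q", "r"], "source": "s", "target": "t",
            "score": scores, "valid": True,
        })
    res = li.differential_interactions(table_for([1.0, 2.0, 3.0]),
                                       table_for([3.0, 2.0, 1.0]))
    deltas = res.shared.set_index("pair")["delta_rank"]
    assert deltas["p"] == pytest.approx(-2 / 3)
    assert deltas["q"] == pytest.approx(0.0)
    assert deltas["r"] == pytest.approx(2 / 3)


def test_gained_lost_reported_separately():
    a = pd.DataFrame({"pair": ["p", "q"], "source": "s", "target": "t",
                      "score": [1.0, 2.0], "valid": [True, True]})
    b = pd.DataFrame({"pair": ["p", "q"], "source": "s", "target": "t",
                      "score": [1.0, np.nan], "valid": [True, False]})
    res = li.differential_interactions(a, b)
    assert list(res.shared["pair"]) == ["p"]
    assert list(res.gained["pair"]) == ["q"]
    assert res.lost.empty
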