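"""Receptor–ligand interaction scoring and differential analysis.

For a gene g in cluster c the component score is

    s(g, c) = z(g, c) * w(c) * f(g, c)

where z is the z-score of the cluster mean expression across clusters
(population sd; a flat gene scores 0), w(c) = n_c / N is the cluster-size
fraction, and f(g, c) is the fraction of cells in c expressing g
(count > 0).  For a ligand unit L in a source cluster and a receptor unit R
in a target cluster the interaction score is

    I = s(L, source) + s(R, target)

with multi-subunit complexes summarized by their limiting subunit (minimum
component score and minimum expressing fraction).  A pairing is valid when
both units are expressed above the configured fraction in their clusters;
per-cluster-pair totals sum I over valid pairs.  Differential analysis
between two conditions replaces scores by fractional quantile ranks
(average rank for ties, normalized to (0, 1]) within each condition and
takes their difference for interactions valid in both conditions;
interactions valid in only one condition are reported as gained/lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = ["LRDatabase", "InteractionParams", "component_score",
           "score_interactions", "top_connections", "differential_interactions",
           "DifferentialResult"]

COMPLEX_SEP = "_"


@dataclass(frozen=True)
class LRDatabase:
    """Ligand–receptor pair list; units are tuples of subunit gene symbols."""

    pairs: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    source_tag: str = "custom"

    def __post_init__(self) -> None:
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError("empty ligand or receptor unit")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate ligand-receptor pairs")

    @staticmethod
    def from_frame(frame: pd.DataFrame, source_tag: str = "custom") -> "LRDatabase":
        pairs = tuple(
            (tuple(row.source.split(COMPLEX_SEP)), tuple(row.target.split(COMPLEX_SEP)))
            for row in frame.itertuples())
        return LRDatabase(pairs=pairs, source_tag=source_tag)

    @staticmethod
    def unit_name(unit: tuple[str, ...]) -> str:
        return COMPLEX_SEP.join(unit)


@dataclass(frozen=True)
class InteractionParams:
    #: a unit is valid when its expressing fraction is strictly greater
    min_expressing_fraction: float = 0.0
    complex_rule: str = "min_subunit"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_expressing_fraction < 1.0:
            raise ValueError("min_expressing_fraction must be in [0, 1)")
        if self.complex_rule != "min_subunit":
            raise ValueError(f"unknown complex_rule {self.complex_rule!r}")


def _cluster_profiles(adata: ad.AnnData, cluster_key: str
                      ) -> tuple[list[str], pd.DataFrame, pd.DataFrame, np.ndarray]:
    labels = adata.obs[cluster_key].astype(str).to_numpy()
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("component scores need at least two clusters")
    X = sparse.csr_matrix(adata.X).astype(float)
    means, fracs, sizes = [], [], []
    for c in clusters:
        mask = labels == c
        sub = X[mask]
        means.append(np.asarray(sub.mean(axis=0)).ravel())
        fracs.append(np.asarray((sub > 0).sum(axis=0)).ravel() / mask.sum())
        sizes.append(int(mask.sum()))
    means = pd.DataFrame(np.vstack(means), index=clusters, columns=adata.var_names)
    fracs = pd.DataFrame(np.vstack(fracs), index=clusters, columns=adata.var_names)
    return clusters, means, fracs, np.asarray(sizes, dtype=float)


def component_score(adata: ad.AnnData, cluster_key: str = "cluster",
                    gene: str | None = None) -> pd.DataFrame | pd.Series:
    """Component score table (clusters x genes), or one gene's column."""
    clusters, means, fracs, sizes = _cluster_profiles(adata, cluster_key)
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=0)
    z = (means - mu).div(sd.where(sd > 0, np.inf), axis=1)
    w = sizes / sizes.sum()
    s = z.mul(w, axis=0) * fracs
    if gene is not None:
        if gene not in s.columns:
            raise ValueError(f"gene {gene!r} not in the matrix")
        return s[gene]
    return s


def score_interactions(adata: ad.AnnData, db: LRDatabase,
                       p: InteractionParams | None = None,
                       cluster_key: str = "cluster"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every (pair, source cluster, target cluster) combination.

    Returns (table, aggregates): the per-pairing table with component
    scores, expressing fractions, validity flags and I = s_L + s_R, and the
    per-cluster-pair totals T(source, target) over valid rows.  Pairs whose
    genes are absent from the matrix are marked untestable and excluded
    from aggregates.
    """
    p = p or InteractionParams()
    clusters, means, fracs, sizes = _cluster_profiles(adata, cluster_key)
    s = component_score(adata, cluster_key)
    rows = []
    for lig, rec in db.pairs:
        pair = f"{LRDatabase.unit_name(lig)}->{LRDatabase.unit_name(rec)}"
        missing = [g for g in lig + rec if g not in s.columns]
        if missing:
            warnings.warn(f"pair {pair} untestable: missing genes {missing}")
            for c_s in clusters:
                for c_t in clusters:
                    rows.append({"pair": pair, "source": c_s, "target": c_t,
                                 "s_ligand": np.nan, "s_receptor": np.nan,
                                 "score": np.nan, "ligand_fraction": np.nan,
                                 "receptor_fraction": np.nan, "valid": False,
                                 "untestable": True})
            continue
        s_lig = s[list(lig)].min(axis=1)  # limiting subunit
        s_rec = s[list(rec)].min(axis=1)
        f_lig = fracs[list(lig)].min(axis=1)
        f_rec = fracs[list(rec)].min(axis=1)
        for c_s in clusters:
            for c_t in clusters:
                valid = bool(f_lig[c_s] > p.min_expressing_fraction
                             and f_rec[c_t] > p.min_expressing_fraction)
                rows.append({
                    "pair": pair, "source": c_s, "target": c_t,
                    "s_ligand": s_lig[c_s], "s_receptor": s_rec[c_t],
                    "score": s_lig[c_s] + s_rec[c_t] if valid else np.nan,
                    "ligand_fraction": f_lig[c_s], "receptor_fraction": f_rec[c_t],
                    "valid": valid, "untestable": False,
                })
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    agg = (valid.groupby(["source", "target"], sort=True)["score"].sum()
           .rename("total_score").reset_index())
    return table, agg


def top_connections(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Per cluster, the k strongest ligand units (as source) and receptor
    units (as target), ranked by the maximum score over partners."""
    valid = table[table["valid"]].copy()
    if valid.empty:
        return pd.DataFrame(columns=["cluster", "role", "unit", "best_score"])
    valid["ligand_unit"] = valid["pair"].str.split("->").str[0]
    valid["receptor_unit"] = valid["pair"].str.split("->").str[1]
    out = []
    for role, cluster_col, unit_col in (("ligand", "source", "ligand_unit"),
                                        ("receptor", "target", "receptor_unit")):
        best = (valid.groupby([cluster_col, unit_col], sort=True)["score"].max()
                .rename("best_score").reset_index())
        for cluster, grp in best.groupby(cluster_col, sort=True):
            top = grp.sort_values(["best_score", unit_col],
                                  ascending=[False, True], kind="stable").head(k)
            for row in top.itertuples():
                out.append({"cluster": cluster, "role": role,
                            "unit": getattr(row, unit_col),
                            "best_score": row.best_score})
    return pd.DataFrame(out)


@dataclass
class DifferentialResult:
    shared: pd.DataFrame  # quantile-rank differences for jointly valid rows
    gained: pd.DataFrame  # valid only in condition A
    lost: pd.DataFrame    # valid only in condition B


def _quantile_ranks(table: pd.DataFrame) -> pd.Series:
    valid = table[table["valid"]]
    ranks = stats.rankdata(valid["score"].to_numpy(), method="average")
    return pd.Series(ranks / len(valid), index=valid.index)


def differential_interactions(table_a: pd.DataFrame, table_b: pd.DataFrame
                              ) -> DifferentialResult:
    """Quantile-rank differences of interaction scores between conditions.

    Scores are replaced by fractional ranks r = rank(I)/N within each
    condition (average rank for ties, N = that condition's valid rows), and
    Δ = r_A − r_B is reported for interactions valid in both conditions.
    """
    key = ["pair", "source", "target"]
    a = table_a[table_a["valid"]].copy()
    b = table_b[table_b["valid"]].copy()
    a["rank"] = _quantile_ranks(table_a)
    b["rank"] = _quantile_ranks(table_b)
    merged = a.merge(b, on=key, suffixes=("_a", "_b"), how="outer", indicator=True)
    shared = merged[merged["_merge"] == "both"]
    if shared.empty:
        warnings.warn("no interaction is valid in both conditions")
    shared = shared[key + ["score_a", "score_b", "rank_a", "rank_b"]].copy()
    shared["delta_rank"] = shared["rank_a"] - shared["rank_b"]
    gained = merged[merged["_merge"] == "left_only"][key + ["score_a", "rank_a"]]
    lost = merged[merged["_merge"] == "right_only"][key + ["score_b", "rank_b"]]
    return DifferentialResult(shared=shared.reset_index(drop=True),
                              gained=gained.reset_index(drop=True),
                              lost=lost.reset_index(drop=True))
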