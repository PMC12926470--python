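"""Directional over-representation analysis on GMT gene sets.

Up- and down-regulated marker lists are tested separately against each gene
set with a one-sided hypergeometric test, BH-adjusted within each
direction, then integrated by keeping only sets significant (adjusted
p < 0.2) in exactly one direction — pathways enriched for both up- and
down-regulated genes are considered non-directional and dropped.  At most
the top 20 sets per contrast and direction are reported, ordered by
adjusted then raw p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

__all__ = ["EnrichmentParams", "overrepresentation_test", "run_directional",
           "integrate_directions", "select_top"]


@dataclass(frozen=True)
class EnrichmentParams:
    alpha_directional: float = 0.2
    top_k: int = 20
    universe_policy: str = "all_tested_genes"  # or "gmt_union"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_directional < 1.0:
            raise ValueError("alpha_directional must be in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.universe_policy not in ("all_tested_genes", "gmt_union"):
            raise ValueError(f"unknown universe_policy {self.universe_policy!r}")


def overrepresentation_test(gene_list: set[str] | list[str],
                            gene_set: set[str] | list[str],
                            universe: set[str] | list[str]) -> float:
    """Hypergeometric upper-tail p-value P(X >= overlap).

    Population = universe, successes = gene set (intersected with the
    universe), draws = gene list.  The gene list must lie inside the
    universe.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not universe or not gene_list:
        raise ValueError("gene list and universe must be non-empty")
    if not gene_list <= universe:
        raise ValueError("gene list is not a subset of the universe")
    gene_set = set(gene_set) & universe
    overlap = len(gene_list & gene_set)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(gene_set),
                                    len(gene_list)))


def run_directional(up_list: list[str], down_list: list[str],
                    gmt: dict[str, list[str]], universe: list[str] | set[str],
                    params: EnrichmentParams | None = None,
                    *, contrast: str = "contrast") -> pd.DataFrame:
    """Test every gene set against the up and down lists separately.

    BH adjustment is applied within each direction.  Returns a long table
    with one row per (gene_set, direction).
    """
    params = params or EnrichmentParams()
    universe = set(universe)
    up, down = set(up_list) & universe, set(down_list) & universe
    if up & down:
        warnings.warn(f"{len(up & down)} genes appear in both the up and down lists")
    rows = []
    for direction, lst in (("up", up), ("down", down)):
        if not lst:
            warnings.warn(f"{direction} list is empty; direction skipped")
            continue
        names, pvals, meta = [], [], []
        for name in sorted(gmt):
            members = set(gmt[name]) & universe
            overlap = len(lst & members)
            p = overrepresentation_test(lst, members, universe) if members else 1.0
            names.append(name)
            pvals.append(p)
            meta.append((overlap, len(members)))
        from statsmodels.stats.multitest import multipletests
        adj = multipletests(pvals, method="fdr_bh")[1]
        for name, p, a, (ov, size) in zip(names, pvals, adj, meta):
            rows.append({"contrast": contrast, "gene_set": name,
                         "direction": direction, "overlap": ov,
                         "set_size": size, "list_size": len(lst),
                         "universe_size": len(universe),
                         "raw_p": p, "adjusted_p": a})
    return pd.DataFrame(rows)


def integrate_directions(results: pd.DataFrame,
                         params: EnrichmentParams | None = None) -> pd.DataFrame:
    """Keep gene sets significant in exactly one direction.

    A set is retained with direction label d iff adjusted_p < alpha for d
    and not for the other direction; sets significant in both or neither
    are dropped.
    """
    params = params or EnrichmentParams()
    if results.empty:
        return results.assign(retained=pd.Series(dtype=bool))
    keep = []
    for (contrast, gene_set), grp in results.groupby(["contrast", "gene_set"],
                                                     sort=True):
        sig = grp[grp["adjusted_p"] < params.alpha_directional]
        if len(sig) == 1:
            keep.append(sig.assign(retained=True))
    if not keep:
        return results.iloc[0:0].assign(retained=pd.Series(dtype=bool))
    return pd.concat(keep, ignore_index=True)


def select_top(retained: pd.DataFrame,
               params: EnrichmentParams | None = None) -> pd.DataFrame:
    """At most ``top_k`` sets per (contrast, direction).

    Ordered by ascending adjusted p, ties by raw p then gene-set label.
    """
    params = params or EnrichmentParams()
    if retained.empty:
        return retained
    out = []
    for _, grp in retained.groupby(["contrast", "direction"], sort=True):
        ordered = grp.sort_values(["adjusted_p", "raw_p", "gene_set"],
                                  kind="stable")
        out.append(ordered.head(params.top_k))
    return pd.concat(out, ignore_index=True)
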