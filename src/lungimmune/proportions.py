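"""Cell-type composition tables and logit-transformed proportion tests.

Per-sample cell-type proportions are continuity-adjusted with a
Haldane-style correction, (count + 0.5) / (total + 1), so zero-count types
stay finite under the logit transform ln(p / (1 - p)).  Condition
differences are tested per cell type with a two-sided unpaired t-test on
the logit values (pooled-variance Student form by default, Welch by
option) and BH-corrected across cell types.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["compute_proportions", "test_proportions"]


def compute_proportions(obs: pd.DataFrame, *, cell_type_key: str = "cell_type",
                        sample_key: str = "sample",
                        condition_key: str = "condition") -> pd.DataFrame:
    """Per-(sample, cell type) counts, proportions and logit values.

    Every cell type observed anywhere appears for every sample, with count
    zero where absent, so downstream tests see a complete table.
    """
    for key in (cell_type_key, sample_key, condition_key):
        if key not in obs.columns:
            raise ValueError(f"column {key!r} missing from the cell table")
    counts = pd.crosstab(obs[sample_key], obs[cell_type_key])
    if counts.empty or (counts.sum(axis=1) == 0).any():
        raise ValueError("a sample has no cells")
    condition_of = (obs[[sample_key, condition_key]].drop_duplicates()
                    .set_index(sample_key)[condition_key])
    rows = []
    for sample in counts.index:
        total = int(counts.loc[sample].sum())
        for cell_type in counts.columns:
            count = int(counts.loc[sample, cell_type])
            adjusted = (count + 0.5) / (total + 1)
            rows.append({
                "sample": sample,
                "condition": condition_of[sample],
                "cell_type": cell_type,
                "count": count,
                "total": total,
                "proportion": count / total,
                "adjusted_proportion": adjusted,
                "logit": float(np.log(adjusted / (1 - adjusted))),
            })
    return pd.DataFrame(rows)


def test_proportions(table: pd.DataFrame, condition_a: str, condition_b: str,
                     *, equal_var: bool = True) -> pd.DataFrame:
    """Unpaired t-tests on logit proportions, per cell type.

    BH correction is applied across cell types for the condition pair.
    Cell types with fewer than two replicate samples in either condition
    are skipped with a warning.
    """
    rows = []
    for cell_type, grp in table.groupby("cell_type", sort=True):
        a = grp.loc[grp["condition"] == condition_a, "logit"].to_numpy()
        b = grp.loc[grp["condition"] == condition_b, "logit"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"cell type {cell_type!r} skipped: fewer than two "
                          f"replicates ({len(a)} vs {len(b)})")
            continue
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "cell_type": cell_type,
            "condition_pair": f"{condition_a}_vs_{condition_b}",
            "t_statistic": float(res.statistic),
            "degrees_of_freedom": float(res.df),
            "raw_p": float(res.pvalue),
            "mean_logit_difference": float(a.mean() - b.mean()),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adjusted_p"] = multipletests(out["raw_p"], method="fdr_bh")[1]
    return out
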