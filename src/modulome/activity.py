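"""Differential iModulon activity between condition groups.

Activities are the rows of the A matrix (one value per sample). An iModulon is
called significantly different between two sample groups when BOTH conditions
hold: the absolute difference of group means exceeds an activity threshold
(default 5, on the activity scale fixed by unit-norm weight columns) and the
Benjamini–Hochberg FDR of a two-sided Welch t-test falls below the chosen
level. The conjunctive rule makes the call conservative: tiny-but-certain
shifts and large-but-noisy shifts are both rejected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _check_groups(A: pd.DataFrame, group1, group2) -> tuple[list, list]:
    g1, g2 = list(group1), list(group2)
    overlap = set(g1) & set(g2)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    missing = [s for s in g1 + g2 if s not in A.columns]
    if missing:
        raise ValueError(f"samples not in activity matrix: {missing}")
    return g1, g2


def diff_activity(
    A: pd.DataFrame,
    group1,
    group2,
    activity_threshold: float = 5.0,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-iModulon differential activity between two disjoint sample groups.

    Returns a table with mean_diff (group2 − group1), Welch-t p-value, BH FDR,
    the conjunctive `significant` flag, and direction ('up'/'down' for the
    sign of mean_diff).
    """
    g1, g2 = _check_groups(A, group1, group2)
    V1 = A[g1].values
    V2 = A[g2].values
    mean_diff = V2.mean(axis=1) - V1.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(V2, V1, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    fdr = multipletests(p, method="fdr_bh")[1]
    significant = (np.abs(mean_diff) > activity_threshold) & (fdr < fdr_level)
    return pd.DataFrame(
        {
            "imodulon": A.index,
            "mean_diff": mean_diff,
            "p_value": p,
            "fdr": fdr,
            "significant": significant,
            "direction": np.where(mean_diff >= 0, "up", "down"),
        }
    ).set_index("imodulon")


def stage_activity_profile(
    A: pd.DataFrame, metadata: pd.DataFrame, condition_order: list
) -> pd.DataFrame:
    """Mean activity per condition, columns in the requested stage order."""
    known = set(metadata["condition_id"])
    unknown = [c for c in condition_order if c not in known]
    if unknown:
        raise ValueError(f"unknown condition ids: {unknown}")
    cols = {}
    for cond in condition_order:
        samples = metadata.index[metadata["condition_id"] == cond].tolist()
        cols[cond] = A[samples].mean(axis=1)
    return pd.DataFrame(cols)


def activity_correlation(A: pd.DataFrame, imodulon_a: str, imodulon_b: str) -> float:
    """Pearson correlation between two iModulons' activity profiles."""
    return float(np.corrcoef(A.loc[imodulon_a].values, A.loc[imodulon_b].values)[0, 1])
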