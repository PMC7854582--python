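"""Per-gene two-group expression comparison (the AdPCa vs NEPCa contrast).

Welch's unequal-variance t-test per gene on the transformed scale, with
Benjamini-Hochberg q-values reported alongside; significance flags follow
the raw p < alpha convention used for per-gene star annotation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codes import apply_transform
from .io import ValidationError, validate_expression

__all__ = ["compare_groups", "rank_most_changed"]


def compare_groups(
    m: pd.DataFrame,
    meta: pd.Series,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    transform: str = "log2p1",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided per-gene t-test of group_b vs group_a.

    Returns one row per gene ordered by ascending p, with columns
    ``mean_a, mean_b, direction`` (sign of mean_b - mean_a on the
    transformed scale), ``t_statistic, p_value, q_value`` (BH over all
    tested genes) and ``significant_raw`` (p < alpha).  Genes with zero
    variance in both groups and equal means get t=0, p=1.  Welch's test
    by default; ``equal_var=True`` selects the pooled Student variant.
    """
    validate_expression(m)
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    for label in (group_a, group_b):
        if label not in set(meta.values):
            raise ValidationError(f"unknown group label {label!r}")
    a_ids = meta.index[meta == group_a].intersection(m.columns)
    b_ids = meta.index[meta == group_b].intersection(m.columns)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {len(a_ids)} vs {len(b_ids)})"
        )

    A = apply_transform(m.loc[:, a_ids].to_numpy(), transform)
    B = apply_transform(m.loc[:, b_ids].to_numpy(), transform)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=equal_var)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    # Degenerate genes: flat in both groups.  Equal means -> no evidence of
    # change (t=0, p=1); scipy already yields +/-inf, p=0 for unequal means.
    flat = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    degenerate = flat & np.isclose(mean_a, mean_b)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    t = np.nan_to_num(t, nan=0.0)

    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "direction": np.sign(mean_b - mean_a).astype(int),
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "significant_raw": p < alpha,
        },
        index=m.index.copy(),
    )
    out.index.name = "gene"
    return out.sort_values(["p_value", "gene"], kind="mergesort")


def rank_most_changed(results: pd.DataFrame) -> list[str]:
    """Genes ordered by |t| descending; ties broken alphabetically."""
    if results is None or len(results) == 0:
        raise ValueError("no comparison results to rank")
    abs_t = results["t_statistic"].abs().sort_index(kind="mergesort")
    return list(abs_t.sort_values(ascending=False, kind="mergesort").index)
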