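"""Rank-based two-sample comparison of inbreeding coefficients.

The test statistic follows the convention of R's ``wilcox.test``: with
pooled midranks, W = (sum of ranks of the first sample) - n_x(n_x+1)/2,
which equals the Mann-Whitney U of the first sample and satisfies
W(x, y) + W(y, x) = n_x * n_y. Two-sided p-values come from the exact
null distribution when the groups are small (n_x * n_y <= 400) and
tie-free, otherwise from the tie-corrected normal approximation (no
continuity correction by default — configurable, since published W/p
pairs can depend on it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_PRODUCT = 400


def rank_sum_W(x, y, use_continuity: bool = False,
               method: str | None = None) -> tuple[float, float]:
    """Rank-sum statistic W and two-sided p-value for samples x vs y.

    method: None (auto: exact when n_x*n_y <= 400 and no ties, else
    asymptotic), "exact", or "asymptotic".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx, ny = x.size, y.size
    W = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    has_ties = np.unique(pooled).size < pooled.size
    if method is None:
        method = ("exact" if nx * ny <= EXACT_MAX_PRODUCT and not has_ties
                  else "asymptotic")
    if method == "exact" and has_ties:
        raise ValueError("exact p-value is not defined with ties")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=use_continuity)
    return W, float(res.pvalue)


def compare_groups(froh_table: pd.DataFrame,
                   pairs: list[tuple[str, str]],
                   value_col: str = "froh_all",
                   use_continuity: bool = False) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of F_ROH between labelled groups.

    ``froh_table`` needs columns ``group`` and ``value_col``. One row per
    pair: group_x, group_y, n_x, n_y, W, p. P-values are reported raw
    (no multiplicity adjustment), matching how such pairwise contrasts
    are conventionally published.
    """
    groups = froh_table.groupby("group")[value_col]
    available = set(froh_table["group"])
    rows = []
    for gx, gy in pairs:
        for g in (gx, gy):
            if g not in available:
                raise ValueError(f"unknown group {g!r}")
        x = groups.get_group(gx).to_numpy()
        y = groups.get_group(gy).to_numpy()
        W, p = rank_sum_W(x, y, use_continuity=use_continuity)
        rows.append({"group_x": gx, "group_y": gy,
                     "n_x": x.size, "n_y": y.size, "W": W, "p": p})
    return pd.DataFrame(rows)
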