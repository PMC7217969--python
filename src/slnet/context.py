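"""Composite context-independence ranking.

A candidate's cellular score is the variance of its interaction scores
across growth conditions; its genetic score is its suppressor count from
the combinatorial map.  The product ranks candidates ascending: low
variance and few suppressors = context independent.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


def cellular_context_score(gi_scores: Sequence[float], population: bool = False) -> float:
    """Variance of a gene's interaction scores across conditions.

    Sample variance (n-1) by default; translation-invariant.
    """
    vals = np.asarray(gi_scores, dtype=float)
    if vals.size < 2:
        raise ValueError("need scores from >= 2 conditions")
    return float(vals.var(ddof=0 if population else 1))


def composite_rank(entries: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by cellular_score x genetic_score, ascending.

    ``entries`` columns: gene, cellular_score, genetic_score, and
    optionally category.  Genes with a missing genetic score are excluded
    (not imputed).  Adds composite, composite_z (display only) and rank
    (1 = most context independent; ties mean-ranked).
    """
    if entries.empty:
        raise ValueError("no entries to rank")
    df = entries.copy()
    df = df[df["genetic_score"].notna()].copy()
    if df.empty:
        raise ValueError("all entries lack a genetic score")
    if (df["cellular_score"] < 0).any():
        raise ValueError("cellular scores must be >= 0")
    if (df["genetic_score"] < 0).any():
        raise ValueError("genetic scores must be >= 0")
    df["composite"] = df["cellular_score"] * df["genetic_score"]
    sd = df["composite"].std(ddof=1) if len(df) > 1 else 0.0
    if sd and np.isfinite(sd):
        df["composite_z"] = (df["composite"] - df["composite"].mean()) / sd
    else:
        df["composite_z"] = 0.0
    df["rank"] = stats.rankdata(df["composite"], method="average")
    return df.sort_values(["rank", "gene"], kind="mergesort").reset_index(drop=True)


def group_rank_test(
    ranks_a: Iterable[float],
    ranks_b: Iterable[float],
    alternative: str = "less",
    exact_max_n: int = 20,
) -> float:
    """Rank-sum (Mann-Whitney) p that group A sits at smaller ranks.

    Exact permutation enumeration when the combined size is <= 20 (handles
    ties by permuting the observed pooled values); normal approximation
    with tie correction otherwise.  ``alternative`` is "less" (A smaller),
    "greater", or "two-sided".
    """
    a = np.asarray(list(ranks_a), dtype=float)
    b = np.asarray(list(ranks_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n, m = a.size, b.size
    if n + m <= exact_max_n:
        pooled = np.concatenate([a, b])
        obs = a.sum()
        total = comb(n + m, n)
        n_le = n_ge = 0
        for idx in combinations(range(n + m), n):
            s = pooled[list(idx)].sum()
            if s <= obs + 1e-12:
                n_le += 1
            if s >= obs - 1e-12:
                n_ge += 1
        p_less = n_le / total
        p_greater = n_ge / total
        if alternative == "less":
            return p_less
        if alternative == "greater":
            return p_greater
        return min(1.0, 2.0 * min(p_less, p_greater))
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.pvalue)
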