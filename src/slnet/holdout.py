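"""Percentile ranking of held-out screens and top-percentile accuracy."""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AccuracyResult:
    n_tested: int
    n_top: int
    accuracy: float | None  # None when no candidate was tested
    cutoff: float


def percentile_rank(diff_scores: Mapping[str, float]) -> dict[str, float]:
    """Rank genes into percentiles of their differential score.

    percentile(g) = 100 * rank(g) / n with rank 1 at the most negative
    score (strongest mutant-specific lethality); ties share the mean rank.
    Percentiles lie in (0, 100] and are invariant to monotone transforms
    of the scores.
    """
    if len(diff_scores) < 2:
        raise ValueError("need at least 2 genes to rank")
    genes = list(diff_scores)
    values = np.array([diff_scores[g] for g in genes], dtype=float)
    ranks = stats.rankdata(values, method="average")
    pct = 100.0 * ranks / len(genes)
    return dict(zip(genes, pct.tolist()))


def accuracy_at_percentile(
    candidates: Iterable[str], table: Mapping[str, float], cutoff: float = 5.0
) -> AccuracyResult:
    """Fraction of tested candidates at or below the percentile cutoff.

    Candidates absent from the table are excluded from the denominator.
    """
    if not 0.0 < cutoff <= 100.0:
        raise ValueError("cutoff must be in (0, 100]")
    tested = [g for g in set(candidates) if g in table]
    if not tested:
        return AccuracyResult(n_tested=0, n_top=0, accuracy=None, cutoff=cutoff)
    n_top = sum(1 for g in tested if table[g] <= cutoff)
    return AccuracyResult(
        n_tested=len(tested), n_top=n_top, accuracy=n_top / len(tested), cutoff=cutoff
    )
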