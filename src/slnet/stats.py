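"""Shared small statistics: BH step-up FDR and a signed t-score helper."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: cap on -log10(p) so underflowing p-values stay finite
NEGLOG10_CAP = 300.0


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone-enforced and capped at 1.  Input order is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def signed_log10_t(
    treat: np.ndarray, ctrl: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided two-sample t on (treat vs ctrl); returns (S, p).

    S = sign(mean(treat) - mean(ctrl)) * (-log10 p), capped, with S = 0
    when the means are equal or p = 1.  Degenerate zero-variance arms with
    identical values give p = 1, S = 0.
    """
    treat = np.asarray(treat, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if treat.size < 2 or ctrl.size < 2:
        raise ValueError("need >= 2 replicates per arm")
    diff = float(treat.mean() - ctrl.mean())
    if np.ptp(treat) == 0 and np.ptp(ctrl) == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff)) * NEGLOG10_CAP, 0.0
    p = float(stats.ttest_ind(treat, ctrl, equal_var=equal_var).pvalue)
    if not np.isfinite(p):
        p = 1.0
    if diff == 0 or p >= 1.0:
        return 0.0, min(p, 1.0)
    neglog = min(-np.log10(max(p, 10.0 ** -NEGLOG10_CAP)), NEGLOG10_CAP)
    return float(np.sign(diff)) * neglog, p
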