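"""Combinatorial-knockdown (query x array) map scoring.

Each query gene gets one plate carrying the full array in quadruplicate.
Counts are normalized to the plate median and Z-scored against the plate's
own distribution; replicate Z values are averaged into one interaction
score per (query, array) pair.  Pairs scoring above +2 are suppressors
(buffering), below -2 aggravating.  Pathway bundles collect a query's
scores against a gene set and test their mean against zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 2.0

EMAP_COLUMNS = ["plate_id", "query_gene", "array_gene", "replicate", "count"]


def emap_normalize(counts, robust: bool = False) -> np.ndarray:
    """Plate normalization: count / plate median, then Z within the plate.

    Z uses the population SD of the normalized values (median/MAD variant
    behind ``robust``); a zero-spread plate yields all-zero Z.  Invariant
    to multiplying every count on the plate by a constant.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty plate")
    if counts.size < 3:
        raise ValueError("plate must have >= 3 wells")
    med = np.median(counts)
    if med == 0:
        raise ValueError("plate median is zero")
    values = counts / med
    if robust:
        center = np.median(values)
        scale = np.median(np.abs(values - center)) * 1.4826
    else:
        center = values.mean()
        scale = values.std()  # population SD
    if scale == 0:
        return np.zeros_like(values)
    return (values - center) / scale


def zscore_plates(table: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """Apply :func:`emap_normalize` per plate; adds a ``z`` column."""
    missing = [c for c in EMAP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"E-MAP table missing columns: {missing}")
    out = table.copy()
    out["z"] = np.nan
    for plate, idx in out.groupby("plate_id").groups.items():
        out.loc[idx, "z"] = emap_normalize(out.loc[idx, "count"].to_numpy(), robust=robust)
    return out


@dataclass
class EmapScore:
    query_gene: str
    array_gene: str
    replicate_zs: tuple[float, ...]
    z_mean: float
    incomplete: bool

    @property
    def call(self) -> str:
        if self.z_mean > DEFAULT_CUTOFF:
            return "positive"
        if self.z_mean < -DEFAULT_CUTOFF:
            return "negative"
        return "neutral"


def average_replicates(z_table: pd.DataFrame, n_expected: int = 4) -> pd.DataFrame:
    """Mean Z per (query, array) pair over replicate wells.

    Pairs missing replicates are averaged over what is present and
    flagged ``incomplete``.  Returns a frame with query_gene, array_gene,
    z_mean, n_reps, incomplete.
    """
    if z_table.empty:
        raise ValueError("no replicate Z values to average")
    grouped = z_table.groupby(["query_gene", "array_gene"])["z"]
    out = grouped.agg(z_mean="mean", n_reps="size").reset_index()
    out["incomplete"] = out["n_reps"] < n_expected
    n_flagged = int(out["incomplete"].sum())
    if n_flagged:
        logger.warning("%d pairs averaged over < %d replicates", n_flagged, n_expected)
    return out


def call_interactions(scores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> tuple[pd.DataFrame, dict]:
    """Threshold mean Z into positive / negative / neutral calls.

    Returns the annotated frame and a summary: n_pairs, n_positive,
    n_negative, strong_fraction = (pos + neg) / pairs.
    """
    out = scores.copy()
    out["call"] = np.where(
        out["z_mean"] > cutoff, "positive", np.where(out["z_mean"] < -cutoff, "negative", "neutral")
    )
    n_pos = int((out["call"] == "positive").sum())
    n_neg = int((out["call"] == "negative").sum())
    n_pairs = len(out)
    summary = {
        "n_pairs": n_pairs,
        "n_positive": n_pos,
        "n_negative": n_neg,
        "strong_fraction": (n_pos + n_neg) / n_pairs if n_pairs else 0.0,
    }
    return out, summary


def suppressor_counts(scores: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF) -> tuple[pd.Series, float]:
    """Per-query count of array genes with mean Z above the cutoff.

    Returns the per-query counts (every query present, zeros kept) and
    their mean across queries.
    """
    pos = scores[scores["z_mean"] > cutoff]
    counts = pos.groupby("query_gene").size()
    counts = counts.reindex(sorted(scores["query_gene"].unique()), fill_value=0)
    mean = float(counts.mean()) if len(counts) else 0.0
    return counts, mean


def pathway_bundle_test(
    scores: pd.DataFrame,
    pathways: GeneSetCollection,
    min_members: int = 3,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided one-sample t of a query's member scores against zero.

    One row per (query, pathway) with >= ``min_members`` scored array
    genes: n, mean Z, p, direction (sign of the mean; neutral at 0) and a
    significance flag at ``alpha``.
    """
    rows = []
    for query, sub in scores.groupby("query_gene"):
        by_array = sub.set_index("array_gene")["z_mean"]
        for name, _, genes in pathways.items():
            members = by_array.loc[by_array.index.intersection(genes)]
            if len(members) < min_members:
                logger.debug("query %s x %s: %d members < %d, skipped", query, name, len(members), min_members)
                continue
            vals = members.to_numpy(dtype=float)
            if np.ptp(vals) == 0 and vals[0] == 0:
                p = 1.0
            else:
                p = float(stats.ttest_1samp(vals, 0.0).pvalue)
                if not np.isfinite(p):
                    p = 1.0
            mean = float(vals.mean())
            direction = "positive" if mean > 0 else "negative" if mean < 0 else "neutral"
            rows.append(
                {
                    "query_gene": query, "pathway": name, "n_members": len(members),
                    "mean_z": mean, "p": p, "direction": direction, "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows, columns=["query_gene", "pathway", "n_members", "mean_z", "p", "direction", "significant"])
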