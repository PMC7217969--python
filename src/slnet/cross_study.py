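"""Cross-study overlap statistics and network connectivity permutation tests.

Two complementary questions about a pair of screens: do their top-k hit
lists share *genes* (hypergeometric test over the tested universe), and do
their hits share *neighborhoods* in a protein-interaction network (edge
count between hit sets against a resampling null)?
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

from .network import InteractionNetwork, _norm_gene

logger = logging.getLogger(__name__)

GENE_RESAMPLE = "gene-resample"
DEGREE_REWIRE = "degree-rewire"


@dataclass
class ScreenStudy:
    """One screen: tested universe, per-gene scores, ordered top-k hits.

    Lower score = stronger synthetic-lethal evidence (orientation is fixed
    upstream).  ``hits`` is derived; use :func:`top_k_hits`.
    """

    study_id: str
    scores: dict[str, float]
    hits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = {
            g: float(s)
            for g, s in ((_norm_gene(k), v) for k, v in self.scores.items())
            if g is not None
        }
        if not self.scores:
            raise ValueError(f"study {self.study_id}: empty tested universe")
        bad = [h for h in self.hits if h not in self.scores]
        if bad:
            raise ValueError(f"study {self.study_id}: hits not in tested universe: {bad[:5]}")

    @property
    def tested(self) -> frozenset[str]:
        return frozenset(self.scores)

    @classmethod
    def from_tsv(cls, path: str | Path, study_id: str | None = None) -> "ScreenStudy":
        """Read a ranked hit list TSV with columns study_id, gene, score."""
        df = pd.read_csv(path, sep="\t")
        if study_id is None:
            study_id = str(df["study_id"].iloc[0])
        else:
            df = df[df["study_id"] == study_id]
        return cls(study_id=study_id, scores=dict(zip(df["gene"], df["score"])))

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"study_id": self.study_id, "gene": list(self.scores), "score": list(self.scores.values())}
        ).sort_values("score", kind="mergesort")
        df["rank"] = range(1, len(df) + 1)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class OverlapResult:
    """Hypergeometric overlap between two hit lists.

    Urn parameters follow the standard model: ``M`` genes in the background,
    ``m`` of them marked (study-2 hits tested in study 1), ``k`` drawn
    (study-1 hits), ``x`` marked among the draw.
    """

    study_a: str
    study_b: str
    x: int
    M: int
    m: int
    k: int
    p_value: float
    tail: str = "geq"  # P(X >= x); "gt" is the strict variant P(X > x)


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    n_perm: int
    p_empirical: float
    p_label: str
    fold_over_null: float
    null_mode: str = GENE_RESAMPLE


def top_k_hits(study: ScreenStudy, k: int) -> list[str]:
    """The k lowest-score genes; boundary ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(study.scores):
        logger.warning(
            "study %s: k=%d exceeds %d tested genes; returning all",
            study.study_id,
            k,
            len(study.scores),
        )
        k = len(study.scores)
    ordered = sorted(study.scores, key=lambda g: (study.scores[g], g))
    return ordered[:k]


def overlap_hypergeom(
    study1: ScreenStudy, study2: ScreenStudy, k: int = 250, strict_tail: bool = False
) -> OverlapResult:
    """Gene-level overlap of the two studies' top-k lists.

    Background = study 1's tested universe; study 2's hits are first
    restricted to genes tested in study 1.  Default tail is P(X >= x);
    ``strict_tail`` gives P(X > x).  Asymmetric in (study1, study2); report
    both orientations when it matters.
    """
    hits1 = set(top_k_hits(study1, k))
    hits2 = set(top_k_hits(study2, k)) & study1.tested
    M = len(study1.tested)
    m = len(hits2)
    n_draw = len(hits1)
    x = len(hits1 & hits2)
    if strict_tail:
        p = float(stats.hypergeom.sf(x, M, m, n_draw))
        tail = "gt"
    else:
        p = float(stats.hypergeom.sf(x - 1, M, m, n_draw))
        tail = "geq"
    return OverlapResult(
        study_a=study1.study_id, study_b=study2.study_id, x=x, M=M, m=m, k=n_draw,
        p_value=min(max(p, 0.0), 1.0), tail=tail,
    )


def count_cross_study_edges(
    net: InteractionNetwork, hits_a: Iterable[str], hits_b: Iterable[str]
) -> int:
    """Edges {u, v} with one endpoint in A and the other in B.

    An edge with both endpoints in the intersection counts once; self-loops
    cannot occur (simple graph).
    """
    a = set(hits_a)
    b = set(hits_b)
    count = 0
    for u, v in net.graph.edges:
        if (u in a and v in b) or (u in b and v in a):
            count += 1
    return count


def _edge_index_arrays(net: InteractionNetwork) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    idx = {g: i for i, g in enumerate(sorted(net.graph.nodes))}
    edges = list(net.graph.edges)
    if not edges:
        return idx, np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    u = np.fromiter((idx[e[0]] for e in edges), dtype=np.intp, count=len(edges))
    v = np.fromiter((idx[e[1]] for e in edges), dtype=np.intp, count=len(edges))
    return idx, u, v


def permutation_null_p(
    net: InteractionNetwork,
    study_a: ScreenStudy,
    study_b: ScreenStudy,
    k: int = 250,
    n_perm: int = 10_000,
    seed: int | None = None,
    null_mode: str = GENE_RESAMPLE,
) -> PermutationResult:
    """Empirical p for the observed cross-study edge count.

    ``gene-resample`` (default): each iteration draws k genes uniformly
    without replacement from each study's tested universe and recounts.
    ``degree-rewire``: hit sets stay fixed; the network is degree-preserving
    rewired each iteration.  p = #{null >= observed} / n_perm, labeled
    "< 1/n_perm" when no null draw reaches the observed count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for st in (study_a, study_b):
        if k > len(st.tested):
            raise ValueError(f"k={k} exceeds tested universe of study {st.study_id}")
    hits_a = set(top_k_hits(study_a, k))
    hits_b = set(top_k_hits(study_b, k))
    observed = count_cross_study_edges(net, hits_a, hits_b)
    rng = np.random.default_rng(seed)

    if null_mode == GENE_RESAMPLE:
        idx, eu, ev = _edge_index_arrays(net)
        n_nodes = len(idx)
        tested_a = np.array([idx[g] for g in sorted(study_a.tested) if g in idx], dtype=np.intp)
        tested_b = np.array([idx[g] for g in sorted(study_b.tested) if g in idx], dtype=np.intp)
        # genes tested but absent from the network can be drawn yet never
        # contribute edges; model them as extra indices past the node range
        n_extra_a = len(study_a.tested) - len(tested_a)
        n_extra_b = len(study_b.tested) - len(tested_b)
        pool_a = np.concatenate([tested_a, n_nodes + np.arange(n_extra_a)])
        pool_b = np.concatenate([tested_b, n_nodes + np.arange(n_extra_b)])
        null_counts = np.empty(n_perm, dtype=np.int64)
        in_a = np.zeros(n_nodes + max(n_extra_a, n_extra_b, 1), dtype=bool)
        in_b = np.zeros_like(in_a)
        for i in range(n_perm):
            draw_a = rng.choice(pool_a, size=k, replace=False)
            draw_b = rng.choice(pool_b, size=k, replace=False)
            in_a[draw_a] = True
            in_b[draw_b] = True
            null_counts[i] = int(
                np.count_nonzero((in_a[eu] & in_b[ev]) | (in_b[eu] & in_a[ev]))
            )
            in_a[draw_a] = False
            in_b[draw_b] = False
    elif null_mode == DEGREE_REWIRE:
        null_counts = np.empty(n_perm, dtype=np.int64)
        base = net.graph
        n_swap = max(1, 10 * base.number_of_edges())
        for i in range(n_perm):
            g = base.copy()
            try:
                nx.double_edge_swap(
                    g, nswap=n_swap, max_tries=n_swap * 20,
                    seed=int(rng.integers(2**31 - 1)),
                )
            except nx.NetworkXError:
                pass  # too few edges to swap; null equals observed graph
            rewired = InteractionNetwork(g)
            null_counts[i] = count_cross_study_edges(rewired, hits_a, hits_b)
    else:
        raise ValueError(f"unknown null_mode: {null_mode!r}")

    n_geq = int(np.count_nonzero(null_counts >= observed))
    p = n_geq / n_perm
    label = f"< {1 / n_perm:g}" if n_geq == 0 else f"{p:g}"
    null_mean = float(null_counts.mean())
    fold = float(observed / null_mean) if null_mean > 0 else float("inf") if observed else 0.0
    return PermutationResult(
        observed=observed, null_counts=null_counts, n_perm=n_perm,
        p_empirical=p, p_label=label, fold_over_null=fold, null_mode=null_mode,
    )
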