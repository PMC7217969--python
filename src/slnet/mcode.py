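"""Dense-module discovery by MCODE-style core-weighted seed expansion.

Vertices are weighted by the highest k-core of their closed neighborhood
(core number times core density), modules grow greedily from high-weight
seeds, and surviving modules are filtered for multi-study hit support and
tested for gene-set enrichment.
"""

from __future__ import annotations

import logging
from collections import deque
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .network import GeneSetCollection, InteractionNetwork
from .cross_study import ScreenStudy
from .stats import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class McodeParams:
    """Clustering knobs; defaults follow the algorithm's published defaults."""

    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # vertex weight percentage (VWP)
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ValueError("cutoffs must be >= 0")


@dataclass
class ModuleResult:
    genes: frozenset[str]
    mcode_score: float
    studies_present: frozenset[str] = frozenset()
    enrichments: list[dict] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.genes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The k-core with maximal k of ``g`` (g assumed nonempty, simple)."""
    core = nx.core_number(g)
    k_max = max(core.values())
    nodes = [v for v, c in core.items() if c >= k_max]
    return k_max, g.subgraph(nodes)


def mcode_vertex_weights(
    net: InteractionNetwork, params: McodeParams | None = None
) -> dict[str, float]:
    """Weight each vertex by (core number) x (density) of the densest core
    of its closed neighborhood; vertices below the degree cutoff get 0."""
    params = params or McodeParams()
    g = net.graph
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree[v] < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph([v, *g.neighbors(v)])
        k, core = _highest_k_core(nbhd)
        weights[v] = k * _density(core)
    return weights


def _haircut(g: nx.Graph) -> nx.Graph:
    """Iteratively strip degree-1 vertices (tree-like appendages)."""
    g = g.copy()
    while True:
        leaves = [v for v in g.nodes if g.degree[v] <= 1 and g.number_of_nodes() > 1]
        if not leaves:
            return g
        g.remove_nodes_from(leaves)


def mcode_find_modules(
    net: InteractionNetwork, params: McodeParams | None = None
) -> list[ModuleResult]:
    """Greedy seeded expansion into disjoint dense modules.

    Seeds are taken in descending weight order (ties: lexicographic); a
    breadth-first front admits unassigned neighbors whose weight is at
    least seed_weight * (1 - VWP), down to ``max_depth`` hops.  Modules
    without a k-core (k=2 by default) are discarded; haircut strips
    degree-1 members.  Score = density x node count.
    """
    params = params or McodeParams()
    g = net.graph
    weights = mcode_vertex_weights(net, params)
    assigned: set[str] = set()
    raw_modules: list[set[str]] = []

    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = deque([(seed, 0)])
        while frontier:
            v, depth = frontier.popleft()
            if depth >= params.max_depth:
                continue
            for u in sorted(g.neighbors(v)):
                if u in assigned or u in members:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        assigned |= members
        raw_modules.append(members)

    results: list[ModuleResult] = []
    for members in raw_modules:
        sub = g.subgraph(members)
        core = nx.k_core(sub, k=params.k_core)
        if core.number_of_nodes() == 0:
            continue
        kept = _haircut(sub) if params.haircut else sub
        if kept.number_of_nodes() < 2:
            continue
        score = _density(kept) * kept.number_of_nodes()
        results.append(ModuleResult(genes=frozenset(kept.nodes), mcode_score=score))
    results.sort(key=lambda m: (-m.mcode_score, -m.size, min(m.genes)))
    return results


def filter_multistudy_modules(
    modules: Iterable[ModuleResult],
    studies: Sequence[ScreenStudy],
    min_studies: int = 2,
) -> list[ModuleResult]:
    """Keep modules containing hit genes from >= ``min_studies`` studies."""
    kept = []
    for mod in modules:
        present = frozenset(
            st.study_id for st in studies if mod.genes & set(st.hits)
        )
        if len(present) >= min_studies:
            kept.append(
                ModuleResult(
                    genes=mod.genes,
                    mcode_score=mod.mcode_score,
                    studies_present=present,
                    enrichments=list(mod.enrichments),
                )
            )
    return kept


def enrich_module(
    module: ModuleResult,
    collection: GeneSetCollection,
    background: Iterable[str],
) -> list[dict]:
    """Upper-tail hypergeometric enrichment of the module in each gene set.

    p-values are Benjamini-Hochberg adjusted across the sets tested for
    this module (in place of the original web tool's proprietary scheme).
    """
    bg = frozenset(background)
    missing = module.genes - bg
    if missing:
        raise ValueError(f"background missing module genes: {sorted(missing)[:5]}")
    rows = []
    for name, _, genes in collection.items():
        marked = genes & bg
        x = len(module.genes & marked)
        p = float(stats.hypergeom.sf(x - 1, len(bg), len(marked), len(module.genes)))
        rows.append({"set_name": name, "overlap": x, "p": min(p, 1.0)})
    if rows:
        qs = bh_fdr(np.array([r["p"] for r in rows]))
        for r, q in zip(rows, qs):
            r["adjusted_p"] = float(q)
    rows.sort(key=lambda r: (r["p"], r["set_name"]))
    return rows


def extract_network_sl_genes(
    filtered_modules: Sequence[ModuleResult],
    input_hits: Iterable[str] = (),
) -> dict[str, dict]:
    """Union of genes over retained modules with per-gene annotation.

    Each gene maps to ``{"modules": [indices], "was_in_input_hits": bool}``
    so the novel fraction (genes absent from every input hit list) falls
    out directly.
    """
    hit_pool = set(input_hits)
    out: dict[str, dict] = {}
    for i, mod in enumerate(filtered_modules):
        for gene in mod.genes:
            rec = out.setdefault(gene, {"modules": [], "was_in_input_hits": gene in hit_pool})
            rec["modules"].append(i)
    return out


def novel_fraction(annotated: dict[str, dict]) -> float:
    """Fraction of network genes absent from every input hit list."""
    if not annotated:
        raise ValueError("no network genes")
    n_novel = sum(1 for rec in annotated.values() if not rec["was_in_input_hits"])
    return n_novel / len(annotated)
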