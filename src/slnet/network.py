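"""Gene-level interaction networks and named gene-set collections.

The interaction network is an undirected simple graph over uppercased gene
symbols.  Edges carry a set of provenance labels (``complex-derived``,
``functional`` or ``synthetic``) so that merged networks remember where each
interaction came from.  Gene-set collections hold complexes / pathways read
from GMT files and back both clique expansion and enrichment testing.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

COMPLEX_DERIVED = "complex-derived"
FUNCTIONAL = "functional"
SYNTHETIC = "synthetic"


def _norm_gene(symbol: str) -> str | None:
    """Uppercase a gene symbol; blank / non-string symbols map to ``None``."""
    if not isinstance(symbol, str):
        return None
    symbol = symbol.strip().upper()
    return symbol or None


@dataclass
class InteractionNetwork:
    """Undirected simple graph over gene symbols with per-edge provenance.

    Invariants: no self-loops, one entry per unordered pair, every edge
    endpoint is a node.  Backed by :class:`networkx.Graph`; edge attribute
    ``sources`` is a set of provenance labels.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    def edge_sources(self, u: str, v: str) -> set[str]:
        return set(self.graph.edges[u, v]["sources"])

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def add_node(self, gene: str) -> None:
        g = _norm_gene(gene)
        if g is not None:
            self.graph.add_node(g)

    def add_edge(self, u: str, v: str, source: str = SYNTHETIC) -> None:
        """Add an undirected edge, dropping self-loops and blank symbols."""
        a, b = _norm_gene(u), _norm_gene(v)
        if a is None or b is None or a == b:
            return
        if self.graph.has_edge(a, b):
            self.graph.edges[a, b]["sources"].add(source)
        else:
            self.graph.add_edge(a, b, sources={source})

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy())

    def merge(self, other: "InteractionNetwork") -> "InteractionNetwork":
        """Union of two networks; provenance labels are unioned per edge."""
        out = self.copy()
        out.graph.add_nodes_from(other.graph.nodes)
        for u, v, data in other.graph.edges(data=True):
            if out.graph.has_edge(u, v):
                out.graph.edges[u, v]["sources"].update(data["sources"])
            else:
                out.graph.add_edge(u, v, sources=set(data["sources"]))
        return out

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    def to_sif_tsv(self, path: str | Path) -> None:
        """Write edges as TSV: geneA, geneB, comma-joined source labels."""
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\tsources\n")
            for u, v, data in sorted(
                self.graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))
            ):
                a, b = sorted((u, v))
                fh.write(f"{a}\t{b}\t{','.join(sorted(data['sources']))}\n")

    @classmethod
    def from_sif_tsv(cls, path: str | Path) -> "InteractionNetwork":
        net = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            has_sources = len(header) > 2
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                sources = parts[2].split(",") if has_sources and len(parts) > 2 else [SYNTHETIC]
                for s in sources:
                    net.add_edge(parts[0], parts[1], source=s)
        return net


@dataclass
class GeneSetCollection:
    """Named gene sets (complexes / pathways) with an optional background.

    ``sets`` maps set name to ``(description, frozenset of genes)``.  Names
    are unique, symbols uppercased, empty sets rejected.
    """

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] | None = None

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        cleaned = {g for g in (_norm_gene(x) for x in genes) if g is not None}
        n_dropped = len(list(genes)) - len(cleaned) if isinstance(genes, (list, tuple)) else None
        if n_dropped:
            logger.debug("gene set %s: dropped %d unmappable symbols", name, n_dropped)
        if not cleaned:
            raise ValueError(f"gene set {name!r} is empty after normalization")
        self.sets[name] = (description, frozenset(cleaned))

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def items(self):
        for name, (desc, genes) in self.sets.items():
            yield name, desc, genes

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, desc, genes in self.items():
                fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        coll = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    logger.warning("%s:%d: short GMT line skipped", path, lineno)
                    continue
                coll.add(parts[0], parts[2:], description=parts[1])
        return coll


def complexes_to_edges(collection: GeneSetCollection) -> InteractionNetwork:
    """Expand each gene set to a clique; union over sets.

    A set of size 1 contributes its node but no edges.  An empty collection
    is an error.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    net = InteractionNetwork()
    for _, _, genes in collection.items():
        ordered = sorted(genes)
        for g in ordered:
            net.add_node(g)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                net.add_edge(a, b, source=COMPLEX_DERIVED)
    return net


def threshold_weighted_edges(
    edge_table: Iterable[tuple[str, str, float]], min_weight: float = 2.0
) -> InteractionNetwork:
    """Keep edges with weight strictly greater than ``min_weight``.

    Dedupes symmetric duplicates and drops self-loops.  A non-numeric
    weight raises :class:`ValueError` naming the offending row.
    """
    net = InteractionNetwork()
    for i, row in enumerate(edge_table):
        a, b, w = row[0], row[1], row[2]
        try:
            w = float(w)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric weight in edge row {i}: {row!r}") from exc
        if w > min_weight:
            net.add_edge(a, b, source=FUNCTIONAL)
    return net


def restrict_to_seed_incident(net: InteractionNetwork, seeds: Iterable[str]) -> InteractionNetwork:
    """Subnetwork of edges with at least one endpoint in ``seeds``.

    Isolated nodes are removed: every node in the result touches a kept edge.
    """
    seed_set = {g for g in (_norm_gene(s) for s in seeds) if g is not None}
    out = InteractionNetwork()
    for u, v, data in net.graph.edges(data=True):
        if u in seed_set or v in seed_set:
            for s in data["sources"]:
                out.add_edge(u, v, source=s)
    return out


def read_edge_tsv(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a TSV edge list (geneA, geneB[, weight]); missing weight -> 1.0."""
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["geneA", "geneB"]:  # headerless file: first line is data
            fh.seek(0)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            w = float(parts[2]) if len(parts) > 2 and parts[2] != "" else 1.0
            rows.append((parts[0], parts[1], w))
    return rows
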