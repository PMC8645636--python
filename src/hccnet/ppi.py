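"""Physical protein-interaction network handling.

Reads an IID-style edge list of experimentally detected physical
interactions, restricts it to genes expressed in the tissue of interest,
expands consensus seed genes to their first-neighbor subnetwork (induced
subgraph, partner-partner edges included), and applies the interactor-count
seed filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

log = logging.getLogger(__name__)

# tokens that mark a first line as a column header rather than an edge
_HEADER_TOKENS = {
    "symbol1", "symbol2", "gene1", "gene2", "gene_a", "gene_b", "genea",
    "geneb", "source", "target", "protein1", "protein2", "proteina",
    "proteinb", "interactor_a", "interactor_b", "symbol_a", "symbol_b",
    "node1", "node2",
}


@dataclass
class Interactome:
    """Deduplicated undirected simple graph over upper-cased gene symbols."""

    edges: set[tuple[str, str]]  # each stored as a sorted 2-tuple

    _adj: dict[str, set[str]] | None = field(default=None, repr=False, compare=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.adjacency())

    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {}
            for a, b in self.edges:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            self._adj = adj
        return self._adj

    def degree(self, node: str) -> int:
        return len(self.adjacency().get(node, ()))

    def neighbors(self, node: str) -> set[str]:
        return set(self.adjacency().get(node, ()))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adjacency())
        g.add_edges_from(self.edges)
        return g


@dataclass
class TissueFilter:
    """Tissue-expressed gene list plus seeds that are always retained."""

    expressed: set[str]
    always_keep: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.expressed = {g.upper() for g in self.expressed}
        self.always_keep = {g.upper() for g in self.always_keep}

    @property
    def allowed(self) -> set[str]:
        return self.expressed | self.always_keep


@dataclass
class SeedNeighborhood:
    """Seeds, their interactor counts, and the induced first-neighbor graph."""

    seeds: list[str]
    degree_by_seed: dict[str, int]
    graph: nx.Graph


def _norm_edge(a: str, b: str) -> tuple[str, str]:
    a, b = a.upper(), b.upper()
    return (a, b) if a <= b else (b, a)


def read_edges(path: str | Path) -> Interactome:
    """Read a whitespace/tab-delimited two-column edge list.

    A header line is auto-detected and skipped; malformed lines and
    self-pairs are dropped with a logged count; A-B and B-A collapse to one
    undirected edge.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    n_bad = 0
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            fields = line.split()
            if lineno == 0 and len(fields) >= 2 and any(
                f.lower() in _HEADER_TOKENS for f in fields[:2]
            ):
                continue
            if not fields:
                continue
            if len(fields) < 2 or not fields[0] or not fields[1]:
                n_bad += 1
                continue
            a, b = fields[0], fields[1]
            if a.upper() == b.upper():
                n_self += 1
                continue
            edges.add(_norm_edge(a, b))
    if n_bad:
        log.warning("%s: skipped %d malformed lines", path.name, n_bad)
    if n_self:
        log.info("%s: dropped %d self-pairs", path.name, n_self)
    if not edges:
        raise ValueError(f"{path}: no valid edges")
    return Interactome(edges=edges)


def write_edges(net: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol1\tsymbol2\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                out.add(g.upper())
    return out


def apply_tissue_filter(net: Interactome, f: TissueFilter) -> Interactome:
    """Keep an edge iff both endpoints are tissue-expressed (or seeds)."""
    if not f.expressed:
        raise ValueError("tissue-expressed gene set is empty")
    allowed = f.allowed
    kept = {e for e in net.edges if e[0] in allowed and e[1] in allowed}
    log.info("tissue filter: %d -> %d edges", len(net.edges), len(kept))
    return Interactome(edges=kept)


def build_neighborhood(net: Interactome, seeds: list[str]) -> SeedNeighborhood:
    """Seeds plus all first neighbors, as the induced subgraph of *net*.

    Partner-partner edges are included; seed interactor counts are taken on
    the full (tissue-filtered) interactome, not the induced subgraph.
    """
    if not seeds:
        raise ValueError("seed list is empty")
    seeds = [s.upper() for s in seeds]
    adj = net.adjacency()
    present = [s for s in seeds if s in adj]
    missing = [s for s in seeds if s not in adj]
    if missing:
        log.warning("%d/%d seeds absent from interactome: %s",
                    len(missing), len(seeds), ", ".join(sorted(missing)[:10]))
    if not present:
        raise ValueError("no seed is present in the interactome")

    node_set: set[str] = set(present)
    for s in present:
        node_set.update(adj[s])
    g = nx.Graph()
    g.add_nodes_from(sorted(node_set))
    for a, b in net.edges:
        if a in node_set and b in node_set:
            g.add_edge(a, b)
    degree_by_seed = {s: len(adj[s]) for s in present}
    return SeedNeighborhood(seeds=present, degree_by_seed=degree_by_seed, graph=g)


def filter_seeds_by_degree(nb: SeedNeighborhood, min_degree: int) -> list[str]:
    """Seeds with at least *min_degree* interactors (inclusive), sorted by
    descending degree then symbol."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    kept = [s for s, d in nb.degree_by_seed.items() if d >= min_degree]
    kept.sort(key=lambda s: (-nb.degree_by_seed[s], s))
    return kept


def degree_knee(nb: SeedNeighborhood) -> tuple[int, int] | None:
    """Largest drop in the descending seed-degree curve.

    Returned as (degree_above, degree_below); purely informational — never
    applied automatically.
    """
    degs = sorted(nb.degree_by_seed.values(), reverse=True)
    if len(degs) < 2:
        return None
    drops = [(degs[i] - degs[i + 1], i) for i in range(len(degs) - 1)]
    best = max(drops, key=lambda t: (t[0], -t[1]))
    i = best[1]
    return (degs[i], degs[i + 1])


def write_neighborhood(nb: SeedNeighborhood, edge_path: str | Path,
                       node_path: str | Path) -> None:
    with open(edge_path, "w") as fh:
        fh.write("symbol1\tsymbol2\n")
        for a, b in sorted(_norm_edge(a, b) for a, b in nb.graph.edges()):
            fh.write(f"{a}\t{b}\n")
    seeds = set(nb.seeds)
    with open(node_path, "w") as fh:
        fh.write("node\tis_seed\tdegree_in_subgraph\tinteractor_count\n")
        for n in sorted(nb.graph.nodes()):
            fh.write(
                f"{n}\t{int(n in seeds)}\t{nb.graph.degree(n)}\t"
                f"{nb.degree_by_seed.get(n, '')}\n"
            )
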