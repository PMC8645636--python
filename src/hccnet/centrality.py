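"""Exact betweenness centrality and node ranking.

Betweenness here follows the classical undirected, unordered-pair,
unnormalized convention: score(v) = sum over unordered pairs {s,t}, s != v
!= t, of sigma_st(v)/sigma_st, where sigma_st counts shortest s-t paths and
sigma_st(v) those passing through v. Pairs in different components
contribute zero. The fast path is Brandes' accumulation (single-source BFS
with dependency back-propagation); an explicit all-shortest-path
enumeration is kept as an independent oracle for small graphs.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx

log = logging.getLogger(__name__)

BRUTEFORCE_MAX_NODES = 15


@dataclass
class CentralityResult:
    scores: dict[str, float]
    ranking: list[tuple[str, float, int]]  # (node, score, 1-based rank)
    top_node: str | None


def _rank(scores: dict[str, float]) -> list[tuple[str, float, int]]:
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(n, s, i + 1) for i, (n, s) in enumerate(ordered)]


def betweenness(g: nx.Graph, normalized: bool = False) -> CentralityResult:
    """Brandes betweenness on an undirected simple graph.

    With ``normalized=True`` scores are scaled by 2/((n-1)(n-2)).
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("graph has no nodes")

    # int-indexed adjacency for speed on networks of a few thousand nodes
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in g.edges():
        ia, ib = index[a], index[b]
        adj[ia].append(ib)
        adj[ib].append(ia)

    bc = [0.0] * n
    for s in range(n):
        stack: list[int] = []
        pred: list[list[int]] = [[] for _ in range(n)]
        sigma = [0.0] * n
        sigma[s] = 1.0
        dist = [-1] * n
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            dv1 = dist[v] + 1
            sv = sigma[v]
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dv1
                    queue.append(w)
                if dist[w] == dv1:
                    sigma[w] += sv
                    pred[w].append(v)
        delta = [0.0] * n
        while stack:
            w = stack.pop()
            coeff = (1.0 + delta[w]) / sigma[w]
            for v in pred[w]:
                delta[v] += sigma[v] * coeff
            if w != s:
                bc[w] += delta[w]

    scale = 0.5  # directed accumulation counted each unordered pair twice
    if normalized:
        scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    scores = {nodes[i]: bc[i] * scale for i in range(n)}

    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    if len(sizes) > 1:
        log.info("graph has %d components (sizes %s...)", len(sizes), sizes[:5])

    ranking = _rank(scores)
    return CentralityResult(scores=scores, ranking=ranking,
                            top_node=ranking[0][0] if ranking else None)


def _all_shortest_paths(adj: dict, s, t) -> list[list]:
    """All geodesics s->t via BFS predecessor DAG; [] if disconnected."""
    dist = {s: 0}
    pred: dict = {s: []}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                pred[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                pred[w].append(v)
    if t not in dist:
        return []
    paths: list[list] = []

    def back(v, acc):
        if v == s:
            paths.append(list(reversed(acc + [v])))
            return
        for p in pred[v]:
            back(p, acc + [v])

    back(t, [])
    return paths


def betweenness_bruteforce(g: nx.Graph) -> dict[str, float]:
    """Betweenness by explicit enumeration of every shortest path per pair.

    Deliberately naive; refuses graphs larger than BRUTEFORCE_MAX_NODES.
    """
    n = g.number_of_nodes()
    if n > BRUTEFORCE_MAX_NODES:
        raise ValueError(
            f"brute-force enumeration limited to {BRUTEFORCE_MAX_NODES} nodes, got {n}"
        )
    adj = {v: sorted(g.neighbors(v)) for v in g.nodes()}
    bc = {v: 0.0 for v in g.nodes()}
    for s, t in combinations(sorted(g.nodes()), 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        w = 1.0 / len(paths)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += w
    return bc


def rank_nodes(
    res: CentralityResult, restrict_to: list[str] | None = None
) -> list[tuple[str, float, int]]:
    """Descending-score ranking, ties broken by symbol.

    ``restrict_to`` reports ranks among the given nodes only (e.g. seeds).
    """
    scores = res.scores
    if restrict_to is not None:
        keep = {n for n in restrict_to if n in scores}
        scores = {n: scores[n] for n in keep}
    return _rank(scores)


def write_ranking(
    res: CentralityResult,
    path: str | Path,
    seeds: set[str] | None = None,
    degrees: dict[str, int] | None = None,
) -> None:
    seeds = seeds or set()
    degrees = degrees or {}
    with open(path, "w") as fh:
        fh.write("node\tbetweenness\trank\tis_seed\tdegree\n")
        for node, score, rank in res.ranking:
            fh.write(
                f"{node}\t{score:.10g}\t{rank}\t{int(node in seeds)}\t"
                f"{degrees.get(node, '')}\n"
            )
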