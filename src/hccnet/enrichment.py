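"""Pathway over-representation analysis.

One-sided hypergeometric tests of a query gene list against a GMT pathway
collection, with Benjamini-Hochberg FDR control across the tested pathways.
The gene universe defaults to the union of all pathway members; an explicit
measured-gene universe can be supplied instead. Query genes outside the
universe are dropped before testing and counted in the result's attributes
(the "annotated with at least one pathway" convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

log = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Pathway id -> (display name, member gene set)."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.pathways.values():
            out |= members
        return out


def read_gmt(path: str | Path) -> PathwayCollection:
    """Standard GMT dialect: name<TAB>description<TAB>gene1<TAB>gene2...

    Duplicate genes within a line collapse to one; lines with fewer than
    three fields are skipped with a warning.
    """
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3 or not fields[0]:
                if line.strip():
                    n_bad += 1
                continue
            name, desc = fields[0], fields[1]
            genes = frozenset(g.upper() for g in fields[2:] if g)
            if not genes:
                n_bad += 1
                continue
            pathways[name] = (desc, genes)
    if n_bad:
        log.warning("%s: skipped %d malformed GMT lines", path.name, n_bad)
    if not pathways:
        raise ValueError(f"{path}: no pathways parsed")
    return PathwayCollection(pathways=pathways)


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, genes) in coll.pathways.items():
            fh.write("\t".join([pid, desc] + sorted(genes)) + "\n")


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N population, K marked,
    n drawn), evaluated stably via log-gamma."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j>=i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q_sorted
    return out


def enrich(
    query: set[str],
    coll: PathwayCollection,
    universe: set[str] | None = None,
    min_set_size: int = 3,
    max_set_size: int | None = None,
) -> pd.DataFrame:
    """Over-representation of *query* in each pathway of *coll*.

    Returns a DataFrame (pathway, name, k, K, n, N, p, q) sorted by (q, p,
    pathway); ``df.attrs`` carries query_size, query_annotated and
    query_dropped counts. Raises if no query gene lies in the universe.
    """
    if not query:
        raise ValueError("query gene set is empty")
    query = {g.upper() for g in query}
    if universe is None:
        uni = coll.universe
    else:
        uni = {g.upper() for g in universe} & coll.universe
    effective = query & uni
    dropped = len(query) - len(effective)
    if not effective:
        raise ValueError("no query gene is present in the pathway universe")
    if dropped:
        log.info("query: %d/%d genes annotated in universe (%d dropped)",
                 len(effective), len(query), dropped)

    N = len(uni)
    n = len(effective)
    rows = []
    for pid, (name, members) in coll.pathways.items():
        mem = members & uni
        K = len(mem)
        if K < min_set_size:
            continue
        if max_set_size is not None and K > max_set_size:
            continue
        k = len(mem & effective)
        rows.append((pid, name, k, K, n, N, hypergeom_p(k, K, n, N)))
    if not rows:
        raise ValueError("no pathway satisfies the size bounds")
    df = pd.DataFrame(rows, columns=["pathway", "name", "k", "K", "n", "N", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["q", "p", "pathway"], kind="mergesort").reset_index(drop=True)
    df.attrs["query_size"] = len(query)
    df.attrs["query_annotated"] = len(effective)
    df.attrs["query_dropped"] = dropped
    return df
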