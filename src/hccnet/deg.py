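"""Cross-study differential-expression integration by consensus voting.

Each study contributes a table of (gene, fold change, adjusted p-value)
records, the dialect produced by GEO2R-style tumor-vs-normal comparisons.
Genes are filtered per study by significance and fold-change window, votes
are tallied per direction across studies, and genes dysregulated in the
same direction in at least ``min_support`` studies form the consensus set.

Fold changes are on the ratio scale by default (tumor/non-tumor; a gene is
"down" at FC <= 0.5 and "up" at FC >= 1.5). A log2 mode with a symmetric
|log2FC| threshold is provided for array comparisons reported on that scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

log = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"

STUDY_COLUMNS = ("gene", "fold_change", "adj_p")


@dataclass(frozen=True)
class FilterCriteria:
    """Per-study DEG retention rules.

    Significance is strict (adj_p < max_adj_p); the fold-change window is
    inclusive at both bounds (FC <= low_fc is down, FC >= high_fc is up).
    In log2 mode the threshold is strict on |log2FC| and applied with the
    same strict p cut.
    """

    max_adj_p: float = 0.05
    low_fc: float = 0.5
    high_fc: float = 1.5
    scale: str = "ratio"
    log2_abs_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.scale not in ("ratio", "log2"):
            raise ValueError(f"scale must be 'ratio' or 'log2', got {self.scale!r}")
        if not 0.0 < self.max_adj_p <= 1.0:
            raise ValueError("max_adj_p must lie in (0, 1]")
        if self.scale == "ratio" and not 0.0 < self.low_fc < 1.0 < self.high_fc:
            raise ValueError("ratio scale requires 0 < low_fc < 1 < high_fc")
        if self.scale == "log2" and self.log2_abs_threshold <= 0:
            raise ValueError("log2_abs_threshold must be positive")


@dataclass
class StudyTable:
    """One study's differential-expression records."""

    study_id: str
    records: pd.DataFrame  # columns: gene, fold_change, adj_p

    def __post_init__(self) -> None:
        missing = [c for c in STUDY_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"study {self.study_id!r} missing columns {missing}")


@dataclass(frozen=True)
class VoteSummary:
    """Direction-consistent vote tally for one gene across studies."""

    gene: str
    support_up: int
    support_down: int
    n_studies: int

    @property
    def consensus_direction(self) -> str:
        if self.support_up > self.support_down:
            return UP
        if self.support_down > self.support_up:
            return DOWN
        return NONE

    @property
    def consensus_support(self) -> int:
        return max(self.support_up, self.support_down)


def read_study_table(path: str | Path, study_id: str | None = None) -> StudyTable:
    """Read a tab-delimited study table with header gene/fold_change/adj_p."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    if study_id is None:
        study_id = path.stem
    return StudyTable(study_id=study_id, records=df[list(STUDY_COLUMNS)].copy())


def _collapse_probes(df: pd.DataFrame) -> pd.DataFrame:
    # multi-probe rows for one gene collapse to the most significant row
    df = df.sort_values(["adj_p", "gene"], kind="mergesort")
    return df.drop_duplicates(subset="gene", keep="first")


def filter_degs(
    table: StudyTable, criteria: FilterCriteria = FilterCriteria()
) -> list[tuple[str, str]]:
    """Apply significance + fold-change filters; return (gene, direction) pairs.

    Non-positive fold changes on the ratio scale are rejected with a logged
    warning rather than raising.
    """
    if table.records.empty:
        raise ValueError(f"study {table.study_id!r} has no records")
    df = _collapse_probes(table.records)
    gene = df["gene"].astype(str).str.upper()
    fc = pd.to_numeric(df["fold_change"])
    adj_p = pd.to_numeric(df["adj_p"])

    out: list[tuple[str, str]] = []
    if criteria.scale == "ratio":
        bad = fc <= 0
        if bad.any():
            log.warning(
                "study %s: rejected %d records with non-positive fold change",
                table.study_id,
                int(bad.sum()),
            )
        sig = (adj_p < criteria.max_adj_p) & ~bad
        for g, f in zip(gene[sig], fc[sig]):
            if f <= criteria.low_fc:
                out.append((g, DOWN))
            elif f >= criteria.high_fc:
                out.append((g, UP))
    else:  # log2 scale: fold_change column holds log2 values
        thr = criteria.log2_abs_threshold
        sig = adj_p < criteria.max_adj_p
        for g, f in zip(gene[sig], fc[sig]):
            if f > thr:
                out.append((g, UP))
            elif f < -thr:
                out.append((g, DOWN))
    return out


def vote_count(
    tables: list[StudyTable], criteria: FilterCriteria = FilterCriteria()
) -> list[VoteSummary]:
    """Tally per-direction passes for every gene appearing in any study."""
    if not tables:
        raise ValueError("at least one study table is required")
    ids = [t.study_id for t in tables]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate study ids (double voting): {dupes}")

    n = len(tables)
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    seen: set[str] = set()
    for t in tables:
        seen.update(t.records["gene"].astype(str).str.upper())
        for g, d in filter_degs(t, criteria):
            if d == UP:
                up[g] = up.get(g, 0) + 1
            else:
                down[g] = down.get(g, 0) + 1
    return [
        VoteSummary(g, up.get(g, 0), down.get(g, 0), n) for g in sorted(seen)
    ]


def select_consensus(
    votes: list[VoteSummary], min_support: int
) -> list[tuple[str, str]]:
    """Genes with an untied majority direction supported by >= min_support studies.

    Sorted by descending support, then gene symbol.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kept = [
        v
        for v in votes
        if v.consensus_direction != NONE and v.consensus_support >= min_support
    ]
    kept.sort(key=lambda v: (-v.consensus_support, v.gene))
    return [(v.gene, v.consensus_direction) for v in kept]


def write_consensus(
    votes: list[VoteSummary], min_support: int, path: str | Path
) -> None:
    rows = []
    by_gene = {v.gene: v for v in votes}
    for g, d in select_consensus(votes, min_support):
        v = by_gene[g]
        rows.append((g, d, v.consensus_support, v.support_up, v.support_down, v.n_studies))
    pd.DataFrame(
        rows,
        columns=["gene", "direction", "support", "support_up", "support_down", "n_studies"],
    ).to_csv(path, sep="\t", index=False)
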