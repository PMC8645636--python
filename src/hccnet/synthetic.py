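"""Synthetic inputs with planted ground truth.

Generators emulate the statistical structure of the pipeline's real-world
inputs — GEO2R-style per-study DEG tables, an IID-style physical
interactome with a liver-expressed gene list, GMT pathway collections, and
a proportional-hazards survival cohort — each with a known planted truth so
every downstream stage is verifiable end to end:

* study tables plant a consensus gene set that passes the significance /
  fold-change filters direction-consistently in at least ``consensus_support``
  of the studies, against a configurable background pass rate;
* interactomes plant a hub as the sole articulation vertex joining two
  partner communities, so its maximal betweenness is structural (not a
  degree artifact);
* pathway collections plant one set heavily overlapping the consensus genes;
* survival cohorts draw exponential event times with hazard multiplied by
  ``true_hr`` in the high-expression subpopulation, under independent
  exponential censoring calibrated to the requested censoring fraction.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .deg import StudyTable, UP, DOWN
from .ppi import Interactome, _norm_edge
from .enrichment import PathwayCollection, write_gmt
from .survival import SurvivalCohort

log = logging.getLogger(__name__)


@dataclass
class SyntheticTruth:
    """What was planted, for downstream recovery checks."""

    consensus_genes: list[tuple[str, str]]  # (gene, "up"|"down")
    hub_gene: str
    enriched_pathways: list[str]
    true_hr: float

    def __post_init__(self) -> None:
        if not self.consensus_genes:
            raise ValueError("consensus_genes must be nonempty")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")


@dataclass
class StudyGenConfig:
    n_studies: int = 19
    n_genes: int = 2000
    consensus_support: int = 10
    noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.consensus_support <= self.n_studies:
            raise ValueError(
                f"consensus_support ({self.consensus_support}) must lie in "
                f"[1, n_studies={self.n_studies}]"
            )
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must lie in [0, 1)")


@dataclass
class CohortGenConfig:
    n_patients: int = 364
    true_hr: float = 0.45
    baseline_hazard: float = 0.025   # per month; exponential median ~27.7 mo
    censor_rate: float = 0.3
    expression_gap: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if self.true_hr <= 0 or self.baseline_hazard <= 0:
            raise ValueError("true_hr and baseline_hazard must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")


def _gene_universe(n_genes: int, planted: list[str]) -> list[str]:
    fillers = [f"G{i:04d}" for i in range(1, n_genes - len(planted) + 1)]
    return list(planted) + fillers


def generate_study_tables(
    cfg: StudyGenConfig, truth: SyntheticTruth
) -> list[StudyTable]:
    """Per-study DEG tables over a shared gene universe.

    Consensus genes pass the default ratio-scale filters in their planted
    direction in >= consensus_support studies; each non-consensus gene
    passes independently per study with probability ``noise_rate`` (random
    direction), capped so that no background gene can reach
    consensus_support direction-consistent passes.
    """
    rng = np.random.default_rng(cfg.seed)
    planted = [g for g, _ in truth.consensus_genes]
    if len(planted) > cfg.n_genes:
        raise ValueError("more consensus genes than the gene universe holds")
    genes = _gene_universe(cfg.n_genes, planted)
    n_genes, n_studies = len(genes), cfg.n_studies
    n_cons = len(planted)
    cap = cfg.consensus_support - 1

    # +1 up / -1 down / 0 not passing, per (gene, study)
    passes = np.zeros((n_genes, n_studies), dtype=np.int8)
    for i, (_, direction) in enumerate(truth.consensus_genes):
        k = int(rng.integers(cfg.consensus_support, n_studies + 1))
        cols = rng.choice(n_studies, size=k, replace=False)
        passes[i, cols] = 1 if direction == UP else -1

    if cfg.noise_rate > 0:
        n_bg = n_genes - n_cons
        counts = np.zeros((n_bg, 2), dtype=int)  # same-direction tallies
        for j in range(n_studies):
            hit = np.nonzero(rng.random(n_bg) < cfg.noise_rate)[0]
            dirs = rng.integers(0, 2, size=hit.size)  # 0 up, 1 down
            for idx, d in zip(hit, dirs):
                if counts[idx, d] >= cap:
                    d = 1 - d
                    if counts[idx, d] >= cap:
                        continue
                counts[idx, d] += 1
                passes[n_cons + idx, j] = 1 if d == 0 else -1

    tables = []
    for j in range(n_studies):
        fc = np.exp2(rng.uniform(-0.55, 0.55, size=n_genes))  # inside (0.5,1.5)
        adj_p = rng.uniform(0.0, 1.0, size=n_genes)
        up = passes[:, j] == 1
        down = passes[:, j] == -1
        fc[up] = rng.uniform(1.5, 4.0, size=int(up.sum()))
        fc[down] = rng.uniform(0.125, 0.5, size=int(down.sum()))
        hit = up | down
        adj_p[hit] = rng.uniform(1e-8, 0.0499, size=int(hit.sum()))
        df = pd.DataFrame({"gene": genes, "fold_change": fc, "adj_p": adj_p})
        tables.append(StudyTable(study_id=f"study_{j + 1:02d}", records=df))
    return tables


def _random_community(nodes: list[str], rng, extra_edge_prob: float = 0.4):
    """Connected random graph: random recursive tree plus extra edges."""
    edges = set()
    for i in range(1, len(nodes)):
        j = int(rng.integers(0, i))
        edges.add(_norm_edge(nodes[i], nodes[j]))
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < extra_edge_prob:
                edges.add(_norm_edge(nodes[i], nodes[j]))
    return edges


def generate_interactome(
    n_nodes: int, hub: str, seed: int = 0
) -> tuple[Interactome, list[str]]:
    """Small interactome in which *hub* is the sole articulation vertex
    joining two otherwise disconnected communities, hence has the uniquely
    maximal betweenness by construction.

    Returns (interactome, tissue gene list); the tissue list covers all
    emitted nodes plus decoy non-expressed symbols.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    rng = np.random.default_rng(seed)
    hub = hub.upper()
    others = [f"G{i:04d}" for i in range(1, n_nodes)]
    half = (n_nodes - 1) // 2
    side_a, side_b = others[:half], others[half:]
    edges = _random_community(side_a, rng) | _random_community(side_b, rng)
    for side in (side_a, side_b):
        k = max(1, len(side) // 3)
        for x in rng.choice(side, size=k, replace=False):
            edges.add(_norm_edge(hub, str(x)))
    tissue = [hub] + others + [f"NX{i:02d}" for i in range(1, 6)]
    return Interactome(edges=edges), tissue


def generate_survival_cohort(cfg: CohortGenConfig) -> SurvivalCohort:
    """Two expression subpopulations separated by ``expression_gap``;
    exponential event times with hazard baseline_hazard * true_hr for the
    high-expression half; independent exponential censoring with rate
    solved so the expected censored fraction equals ``censor_rate``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    high = rng.random(n) < 0.5
    expression = rng.normal(2.0, 0.4, size=n)
    expression[high] += cfg.expression_gap
    lam = np.where(high, cfg.baseline_hazard * cfg.true_hr, cfg.baseline_hazard)
    t_event = rng.exponential(1.0 / lam)

    if cfg.censor_rate > 0:
        lam_vals = np.array([cfg.baseline_hazard, cfg.baseline_hazard * cfg.true_hr])

        def censored_frac(mu):
            return float(np.mean(mu / (lam_vals + mu))) - cfg.censor_rate

        mu = brentq(censored_frac, 1e-10, 1e6)
        t_cens = rng.exponential(1.0 / mu, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)

    sex = rng.choice(["M", "F"], size=n)
    df = pd.DataFrame({
        "patient": [f"P{i:04d}" for i in range(1, n + 1)],
        "time": time,
        "event": event,
        "expression": expression,
        "sex": sex,
    })
    return SurvivalCohort(data=df)


def generate_pathways(
    consensus: list[str],
    rng,
    n_pathways: int = 40,
    filler_pool: list[str] | None = None,
    planted_id: str = "PW_PLANTED",
) -> tuple[PathwayCollection, list[str]]:
    """GMT collection with one planted enriched pathway drawing half its
    members from the consensus genes; the rest draw from the filler pool."""
    if filler_pool is None:
        filler_pool = [f"G{i:04d}" for i in range(1, 1501)]
    n_from_cons = min(20, len(consensus))
    members = list(rng.choice(consensus, size=n_from_cons, replace=False))
    members += list(rng.choice(filler_pool, size=10, replace=False))
    pathways = {planted_id: ("planted enriched set", frozenset(g.upper() for g in members))}
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(15, 81))
        genes = rng.choice(filler_pool, size=size, replace=False)
        pathways[f"PW{i:03d}"] = (f"background set {i}",
                                  frozenset(str(g).upper() for g in genes))
    return PathwayCollection(pathways=pathways), [planted_id]


@dataclass
class FixtureSizes:
    """Knobs for the full demo dataset; defaults are the study conditions."""

    n_studies: int = 19
    consensus_support: int = 10
    n_genes: int = 1500
    noise_rate: float = 0.02
    n_high_seeds: int = 27          # consensus genes planted with >= min_degree partners
    n_low_seeds: int = 13
    partners_per_seed: int = 250
    partner_pool: int = 300         # per community side
    extra_partner_edges: int = 400  # partner-partner edges per side
    n_pathways: int = 40
    n_patients: int = 364
    true_hr: float = 0.45
    censor_rate: float = 0.3
    expression_gap: float = 4.0


def _fixture_interactome(sizes: FixtureSizes, seeds_a, seeds_b, hub, low_seeds, rng):
    """Two partner communities joined only through the hub; every high-degree
    seed gets >= partners_per_seed expressed partners from its own side."""
    pa = [f"PA{i:03d}" for i in range(1, sizes.partner_pool + 1)]
    pb = [f"PB{i:03d}" for i in range(1, sizes.partner_pool + 1)]
    edges: set[tuple[str, str]] = set()

    def attach(seed, pool, k):
        for p in rng.choice(pool, size=k, replace=False):
            edges.add(_norm_edge(seed, str(p)))

    for s in seeds_a:
        attach(s, pa, sizes.partners_per_seed + int(rng.integers(0, 30)))
    for s in seeds_b:
        attach(s, pb, sizes.partners_per_seed + int(rng.integers(0, 30)))
    half = sizes.partners_per_seed // 2
    attach(hub, pa, half)
    attach(hub, pb, sizes.partners_per_seed - half)

    for pool in (pa, pb):
        for _ in range(sizes.extra_partner_edges):
            i, j = rng.choice(len(pool), size=2, replace=False)
            edges.add(_norm_edge(pool[i], pool[j]))

    for i, s in enumerate(low_seeds):
        pool = pa if i % 2 == 0 else pb
        attach(s, pool, int(rng.integers(3, 9)))

    # decoy nodes absent from the tissue list: filtered out downstream
    decoys = [f"NX{i:02d}" for i in range(1, 21)]
    for d in decoys:
        attach(d, pa + pb, 5)

    expressed = set(pa) | set(pb) | set(seeds_a) | set(seeds_b) | set(low_seeds) | {hub}
    tissue = sorted(expressed) + [f"G{i:04d}" for i in range(1, 51)]
    return Interactome(edges=edges), tissue


def generate_dataset(
    outdir: str | Path,
    seed: int = 0,
    sizes: FixtureSizes = None,
) -> SyntheticTruth:
    """Materialize a full demo dataset directory.

    Writes studies/*.tsv, interactome.tsv, tissue_genes.txt, pathways.gmt,
    survival.tsv and truth.json; returns the planted truth.
    """
    sizes = sizes or FixtureSizes()
    outdir = Path(outdir)
    (outdir / "studies").mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    sub = [int(s) for s in root_rng.integers(0, 2**31 - 1, size=8)]

    hub = "HUB1"
    seeds_a = [f"SD{i:02d}" for i in range(1, sizes.n_high_seeds // 2 + 1)]
    seeds_b = [f"SD{i:02d}" for i in range(sizes.n_high_seeds // 2 + 1,
                                           sizes.n_high_seeds)]
    low_seeds = [f"LC{i:02d}" for i in range(1, sizes.n_low_seeds + 1)]
    all_cons = [hub] + seeds_a + seeds_b + low_seeds
    dir_rng = np.random.default_rng(sub[0])
    consensus = [(g, UP if dir_rng.random() < 0.5 else DOWN) for g in all_cons]

    study_cfg = StudyGenConfig(
        n_studies=sizes.n_studies, n_genes=sizes.n_genes,
        consensus_support=sizes.consensus_support,
        noise_rate=sizes.noise_rate, seed=sub[1],
    )
    net_rng = np.random.default_rng(sub[2])
    net, tissue = _fixture_interactome(sizes, seeds_a, seeds_b, hub, low_seeds, net_rng)
    pw_rng = np.random.default_rng(sub[3])
    coll, enriched = generate_pathways(
        [g for g, _ in consensus], pw_rng, n_pathways=sizes.n_pathways,
        filler_pool=[f"G{i:04d}" for i in range(1, sizes.n_genes + 1)],
    )
    cohort = generate_survival_cohort(CohortGenConfig(
        n_patients=sizes.n_patients, true_hr=sizes.true_hr,
        censor_rate=sizes.censor_rate, expression_gap=sizes.expression_gap,
        seed=sub[4],
    ))
    truth = SyntheticTruth(
        consensus_genes=consensus, hub_gene=hub,
        enriched_pathways=enriched, true_hr=sizes.true_hr,
    )

    tables = generate_study_tables(study_cfg, truth)
    for t in tables:
        t.records.to_csv(outdir / "studies" / f"{t.study_id}.tsv",
                         sep="\t", index=False)
    with open(outdir / "interactome.tsv", "w") as fh:
        fh.write("symbol1\tsymbol2\n")
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "tissue_genes.txt", "w") as fh:
        fh.write("\n".join(tissue) + "\n")
    write_gmt(coll, outdir / "pathways.gmt")
    cohort.data.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "consensus_genes": truth.consensus_genes,
                "hub_gene": truth.hub_gene,
                "enriched_pathways": truth.enriched_pathways,
                "true_hr": truth.true_hr,
                "n_high_degree_seeds": sizes.n_high_seeds,
            },
            fh, indent=2, sort_keys=True,
        )
    log.info("fixture dataset written to %s", outdir)
    return truth
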