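"""End-to-end orchestration: DEG integration -> tissue-filtered network ->
betweenness ranking -> pathway enrichment -> survival analysis.

Every stage logs its in/out counts; the run report echoes the
configuration, input checksums and package version so a run is reproducible
byte-for-byte given identical inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .deg import FilterCriteria, read_study_table, vote_count, select_consensus, write_consensus
from .ppi import (TissueFilter, read_edges, read_gene_list, apply_tissue_filter,
                  build_neighborhood, filter_seeds_by_degree, degree_knee,
                  write_neighborhood)
from .centrality import betweenness, rank_nodes, write_ranking
from .enrichment import read_gmt, enrich
from .survival import read_survival_table, best_cutoff_scan, gbw_test, write_km_curve

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    study_dir: str
    interactome_path: str
    tissue_path: str
    gmt_path: str
    survival_path: str
    out_dir: str = "hccnet_out"
    criteria: FilterCriteria = field(default_factory=FilterCriteria)
    min_support: int = 10
    min_degree: int = 250
    alpha: float = 0.05
    survival_test: str = "logrank"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        crit = FilterCriteria(**raw.pop("criteria", {}))
        return cls(criteria=crit, **raw)

    def validate(self) -> None:
        for p in (self.study_dir, self.interactome_path, self.tissue_path,
                  self.gmt_path, self.survival_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        n_studies = len(sorted(Path(self.study_dir).glob("*.tsv")))
        if n_studies == 0:
            raise ValueError(f"no study tables (*.tsv) in {self.study_dir}")
        if self.min_support > n_studies:
            raise ValueError(
                f"min_support ({self.min_support}) exceeds the number of "
                f"study tables ({n_studies})"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_degree < 0:
            raise ValueError("min_degree must be >= 0")
        if self.survival_test not in ("logrank", "gbw"):
            raise ValueError("survival_test must be 'logrank' or 'gbw'")


@dataclass
class RunReport:
    consensus: list  # (gene, direction, support)
    n_studies: int
    seed_degrees: dict
    retained_seeds: list
    top_node: str
    ranking_overall: list   # top rows (node, score, rank)
    ranking_seeds: list
    enrichment: list        # significant pathways (id, k, K, p, q)
    n_pathways_tested: int
    survival: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)


@contextmanager
def _stage(name: str):
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(name, exc) from exc
    log.info("stage %s: done", name)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("integrate"):
        paths = sorted(Path(cfg.study_dir).glob("*.tsv"))
        tables = [read_study_table(p) for p in paths]
        votes = vote_count(tables, cfg.criteria)
        consensus = select_consensus(votes, cfg.min_support)
        log.info("integrate: %d genes voted, %d consensus at support >= %d",
                 len(votes), len(consensus), cfg.min_support)
        if not consensus:
            raise ValueError("empty consensus gene set")
        write_consensus(votes, cfg.min_support, out / "consensus.tsv")
        by_gene = {v.gene: v for v in votes}

    with _stage("network"):
        net = read_edges(cfg.interactome_path)
        tissue = read_gene_list(cfg.tissue_path)
        seeds = [g for g, _ in consensus]
        net_f = apply_tissue_filter(
            net, TissueFilter(expressed=tissue, always_keep=set(seeds))
        )
        nb_all = build_neighborhood(net_f, seeds)
        knee = degree_knee(nb_all)
        if knee:
            log.info("network: largest seed-degree drop %d -> %d", *knee)
        retained = filter_seeds_by_degree(nb_all, cfg.min_degree)
        log.info("network: %d/%d seeds with >= %d interactors",
                 len(retained), len(nb_all.seeds), cfg.min_degree)
        if not retained:
            raise ValueError(f"no seed reaches min_degree={cfg.min_degree}")
        nb = build_neighborhood(net_f, retained)
        write_neighborhood(nb, out / "network_edges.tsv", out / "network_nodes.tsv")

    with _stage("centrality"):
        res = betweenness(nb.graph)
        ranking_seeds = rank_nodes(res, restrict_to=retained)
        write_ranking(res, out / "centrality.tsv", seeds=set(retained),
                      degrees=nb.degree_by_seed)
        log.info("centrality: top node %s (score %.1f) over %d nodes",
                 res.top_node, res.ranking[0][1], len(res.scores))

    with _stage("enrich"):
        coll = read_gmt(cfg.gmt_path)
        enr = enrich({g for g, _ in consensus}, coll)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        sig = enr[enr["q"] < cfg.alpha]
        log.info("enrich: %d/%d pathways at FDR < %g (query: %d/%d annotated)",
                 len(sig), len(enr), cfg.alpha,
                 enr.attrs["query_annotated"], enr.attrs["query_size"])

    with _stage("survival"):
        cohort = read_survival_table(cfg.survival_path)
        scan = best_cutoff_scan(cohort, test=cfg.survival_test)
        low, high = cohort.split(scan.best_cutoff)
        gbw = gbw_test(low["time"], low["event"], high["time"], high["event"])
        write_km_curve(scan.km_low, out / "km_low.tsv")
        write_km_curve(scan.km_high, out / "km_high.tsv")
        with open(out / "cutoff_scan.tsv", "w") as fh:
            fh.write("cutoff\tp\n")
            for c, p in zip(scan.candidate_cutoffs, scan.p_by_cutoff):
                fh.write(f"{c:.10g}\t{p:.6g}\n")
        survival_summary = {
            "best_cutoff": scan.best_cutoff,
            "best_p": scan.best_p,
            "hr_high_vs_low": scan.comparison.hr,
            "ci_low": scan.comparison.ci_low,
            "ci_high": scan.comparison.ci_high,
            "chi2": scan.comparison.chi2,
            "gbw_p": gbw.p,
            "n_low": scan.n_low,
            "n_high": scan.n_high,
            "median_survival_low": scan.km_low.median,
            "median_survival_high": scan.km_high.median,
        }
        log.info("survival: best cutoff %.3g, HR %.3g (%.3g-%.3g), p %.3g",
                 scan.best_cutoff, scan.comparison.hr, scan.comparison.ci_low,
                 scan.comparison.ci_high, scan.best_p)

    provenance = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            **{k: getattr(cfg, k) for k in (
                "study_dir", "interactome_path", "tissue_path", "gmt_path",
                "survival_path", "min_support", "min_degree", "alpha",
                "survival_test")},
            "criteria": dataclasses.asdict(cfg.criteria),
        },
        "input_sha256": {
            "interactome": _sha256(cfg.interactome_path),
            "tissue": _sha256(cfg.tissue_path),
            "gmt": _sha256(cfg.gmt_path),
            "survival": _sha256(cfg.survival_path),
            "studies": {p.name: _sha256(p) for p in paths},
        },
        "counts": {
            "n_studies": len(tables),
            "n_genes_voted": len(votes),
            "n_consensus": len(consensus),
            "n_edges_raw": len(net.edges),
            "n_edges_tissue": len(net_f.edges),
            "n_seeds_retained": len(retained),
            "n_network_nodes": nb.graph.number_of_nodes(),
            "n_network_edges": nb.graph.number_of_edges(),
            "n_pathways_tested": len(enr),
            "n_pathways_significant": len(sig),
            "n_patients": len(cohort),
        },
    }

    report = RunReport(
        consensus=[(g, d, by_gene[g].consensus_support) for g, d in consensus],
        n_studies=len(tables),
        seed_degrees=dict(sorted(nb_all.degree_by_seed.items())),
        retained_seeds=retained,
        top_node=res.top_node,
        ranking_overall=[list(r) for r in res.ranking[:25]],
        ranking_seeds=[list(r) for r in ranking_seeds[:25]],
        enrichment=[[r.pathway, int(r.k), int(r.K), float(r.p), float(r.q)]
                    for r in sig.itertuples()],
        n_pathways_tested=len(enr),
        survival=survival_summary,
        provenance=provenance,
    )
    with open(out / "report.json", "w") as fh:
        fh.write(report.to_json())
    return report
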