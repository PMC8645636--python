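# hccnet

Network-centrality gene prioritization for hepatocellular carcinoma (HCC),
built as a reusable, tested pipeline for computational biologists who want
to go from many tumor-vs-normal differential-expression tables to a ranked
list of network-central candidate genes — and to check whether a candidate
marks survival.

HCC is a strongly male-biased cancer, and one proposed explanation is
estrogen-receptor signaling: integrative analyses of public HCC expression
data have found the estrogen receptor gene *ESR1* to be the most *central*
protein in the disease's interaction network and protective for survival
when highly expressed. `hccnet` implements that style of analysis end to
end:

1. **Consensus voting** — per-study DEG filtering (`adj_p < 0.05`, fold
   change ≤ 0.5 or ≥ 1.5 on the ratio scale) and direction-consistent vote
   counting across studies; genes dysregulated the same way in ≥ 10 of 19
   studies form the consensus set.
2. **Network construction** — an IID-style physical-interaction edge list
   is restricted to liver-expressed genes, consensus seeds are expanded to
   their first-neighbor induced subgraph, and seeds with ≥ 250 interactors
   are retained.
3. **Centrality** — exact unnormalized betweenness
   (score(v) = Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs, Brandes'
   algorithm) ranks the network's bottleneck proteins.
4. **Enrichment** — one-sided hypergeometric over-representation of the
   consensus genes against a GMT pathway collection with
   Benjamini-Hochberg FDR control.
5. **Survival** — Kaplan-Meier curves, log-rank and Gehan-Breslow-Wilcoxon
   tests, a Cox hazard ratio (Breslow ties) for high- vs low-expressing
   patients, with the cutoff chosen by scanning every observed expression
   value between the quartiles for the minimal log-rank p.

A synthetic-data module generates all five input types with *planted*
ground truth (a known consensus set, an articulation-vertex hub, an
enriched pathway, a true hazard ratio), so the whole pipeline is verifiable
without downloading anything.

## Worked example

```bash
$ hccnet make-fixtures demo --seed 7
wrote demo: 40 consensus genes, hub HUB1, true HR 0.45

$ hccnet run-all demo --out demo_out
top gene by betweenness: HUB1
consensus genes: 40; seeds retained: 27
survival: HR 0.503 (0.391-0.648), p 5.94e-08
```

Reading the output: all 40 planted consensus genes were recovered by the
≥ 10/19 vote; exactly the 27 genes planted with ≥ 250 liver-expressed
interactors survive the degree filter; the planted hub `HUB1` — built as
the sole articulation vertex joining the network's two communities — is
ranked #1 by betweenness; and dichotomizing the synthetic cohort (n = 364,
planted hazard ratio 0.45) at the best scanned cutoff estimates
HR ≈ 0.50 (95% CI 0.39–0.65), i.e. high expression protective, with a
log-rank p of 5.9e-08. Stage-by-stage artifacts (consensus table, network
edge/node lists, centrality ranking, enrichment table, KM curves, cutoff
scan, and a `report.json` with input checksums) land in `demo_out/`.

Every stage is also available as a standalone subcommand (`integrate`,
`network`, `centrality`, `enrich`, `survival`) or as library functions
(`hccnet.vote_count`, `hccnet.betweenness`, `hccnet.enrich`,
`hccnet.best_cutoff_scan`, ...).

Note on the best-cutoff scan: the minimum of many correlated log-rank
tests is anticonservative (under a true null it rejects at several times
the nominal rate). The raw minimum is reported to match common practice;
`hccnet.permutation_corrected_p` provides a permutation-calibrated
alternative. See `docs/methods.md` for the full model documentation.

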