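# Methods

`hccnet` re-implements, as a reusable and fully tested pipeline, an
integrative network analysis that prioritizes genes in hepatocellular
carcinoma (HCC): genes consistently dysregulated across many
tumor-vs-non-tumor expression studies are mapped onto a liver-expressed
physical protein-interaction network, ranked by betweenness centrality,
tested for pathway over-representation, and evaluated as survival markers
by expression-dichotomized Kaplan-Meier analysis. This note documents the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic data does and does not establish.

## Cross-study consensus voting

Each study table holds GEO2R-style records (gene, fold change on the
tumor/non-tumor ratio scale, adjusted p-value). A record is a DEG when
`adj_p < 0.05` (strict) and the fold change falls outside the open window
(0.5, 1.5) — boundary fold changes 0.5 and 1.5 are retained (the thresholds
are "at most"/"at least"), while `adj_p = 0.05` is excluded. A log2 mode
(`|log2FC| > 1`, strict, with `p < 0.05`) covers array comparisons reported
on that scale. Per-study, multi-probe rows for one gene collapse to the
most significant row before filtering; the thresholds themselves say
nothing about probe collapse, so this is a package decision.

Votes are tallied per direction; a gene's consensus direction is its
majority direction (ties mean no consensus), and its support is the count
in that direction only. The consensus set is genes with support at or above
`min_support` (default 10, against the default 19 studies). The support
denominator is the absolute study count — a gene absent from a study simply
contributes no vote — because the threshold is stated as a count, not a
fraction of studies measuring the gene.

## Interactome handling

The edge reader ingests a two-column symbol edge list (IID-style), upper-
cases symbols, drops self-pairs, and collapses A-B/B-A duplicates; a header
line is auto-detected. Tissue filtering keeps an edge only when both
endpoints are in the expressed-gene list or in `always_keep` — the seeds
are always kept, since dropping a dysregulated tumor gene for lacking a
liver annotation would defeat the purpose of seeding with it.

Seed expansion takes the seeds plus all first neighbors and forms the
*induced* subgraph — partner-partner edges included. Excluding them would
make every partner a leaf with zero betweenness and degenerate the
centrality ranking. Seed interactor counts are taken on the full
tissue-filtered interactome, not the induced subgraph, and the seed filter
keeps seeds with at least `min_degree` interactors (default 250,
inclusive). A knee report (largest drop in the sorted degree curve) is
logged for transparency but never applied automatically.

## Betweenness centrality

Classical undirected convention: score(v) = Σ over unordered pairs {s,t}
of σ_st(v)/σ_st, unnormalized, unweighted, pairs in different components
contributing zero. The fast path is Brandes' algorithm (single-source BFS
plus dependency back-propagation, O(nm)); `--normalized` applies
2/((n−1)(n−2)) if comparisons across graph sizes are needed, but only rank
order matters for prioritization. An independent brute-force oracle
(explicit enumeration of every geodesic per pair, capped at 15 nodes)
backs the test suite. Ranks are dense 1-based positions after sorting by
descending score with lexicographic tie-breaks; rankings are reported both
over all network nodes and restricted to the seeds, since a prioritization
can reasonably be read either way.

## Pathway over-representation

One-sided hypergeometric tests: for a query of n genes in a universe of N,
a pathway with K members and overlap k gets p = P(X ≥ k),
X ~ Hypergeom(N, K, n), computed by `scipy.stats.hypergeom.sf` (log-gamma
based, stable for extreme tails). The universe defaults to the union of all
pathway members; query genes outside it are dropped and counted (the
"annotated with at least one pathway" convention), and an explicit
measured-gene universe can be supplied. Pathways with fewer than 3
annotated members are not tested (configurable; no upper bound by
default). FDR control is Benjamini-Hochberg step-up,
q_(i) = min_{j≥i} p_(j)·m/j capped at 1, applied across exactly the tested
pathways. The enrichment of a gene list is methodologically parallel to,
not numerically identical with, results from web services whose catalogs
and universes are proprietary.

## Survival analysis

Kaplan-Meier: S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event times;
records censored at an event time remain at risk for it. The median is the
smallest event time with S ≤ 0.5, undefined (NaN) if never reached.

Two-group tests share one counting-process tabulation. At each pooled
event time with n_1, n_2 at risk and d_1, d_2 events (d = d_1+d_2,
n = n_1+n_2):

* log-rank (Mantel-Haenszel): U = Σ (d_1 − d·n_1/n),
  V = Σ d·(n_1/n)(n_2/n)(n−d)/(n−1), χ² = U²/V with 1 df;
* Gehan-Breslow-Wilcoxon: the same with weight w = n per time
  (U = Σ w(·), V = Σ w²(·)), emphasizing early differences.

The hazard ratio for the high- vs low-expression indicator comes from the
Cox partial likelihood with Breslow tie handling, solved by Newton
iteration from β = 0 (tolerance 1e-12, ≤50 iterations; for a binary
covariate the score and information reduce to closed sums over event
times). The 95% CI is exp(β̂ ± 1.96·SE) from the observed information.
Perfect separation or a group with zero events yields a flagged boundary
estimate (HR 0 or ∞, CI undefined) instead of a crash. With no ties,
Breslow and Efron coincide, which is how the implementation is
cross-checked against an independent library.

Best-cutoff dichotomization scans every distinct observed expression value
between the lower and upper quartile (linear-interpolation quantiles; the
quantile rule is a package choice), splits at expression < cutoff vs
≥ cutoff, and keeps the cutoff minimizing the two-group p-value (ties go to
the smaller cutoff; candidates emptying a group are skipped and logged).
The orientation is high-vs-low, so HR < 1 means high expression is
protective. **The scanned minimum p is anticonservative**: under a true
null at n = 364 the scan rejects at α = 0.05 roughly 6-7 times the nominal
rate (measured ≈33% over null replicates, with a median minimum p near
0.09). This mirrors the behavior of popular auto-cutoff survival portals
and is reported as-is; `permutation_corrected_p` provides a min-p
permutation correction (expression permuted against time/event, add-one
estimator) when a calibrated p-value is needed.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed).

**Study tables** plant a consensus set: each planted gene passes the
filters in its planted direction in a uniformly drawn number of studies
between `consensus_support` and `n_studies`; every background gene passes
independently per study with probability `noise_rate` (direction random,
capped so that no background gene can accumulate `consensus_support`
same-direction passes). Passing records draw FC from U(1.5, 4) (up) or
U(0.125, 0.5) (down) with adj_p < 0.05; non-passing records sit strictly
inside the FC window. Defaults: 19 studies, support 10, noise rate 0.02,
2000-gene universe (1500 in the packaged fixture).

**Interactomes** plant the hub as the sole articulation vertex joining two
otherwise disconnected communities, so its betweenness dominance is
structural and specifically tests betweenness rather than degree. The
packaged fixture has 27 high-degree seeds (each with ≥250 expressed
partners drawn from a 300-node pool per community, 13 seeds per side plus
the hub bridging both), 13 low-degree consensus genes (3-8 partners), 400
extra partner-partner edges per side, and decoy nodes absent from the
tissue list to exercise the filter. The partner-pool size keeps the
centrality graph at ~650 nodes so exact betweenness runs in seconds while
preserving the paper-scale degree threshold of 250.

**Pathway collections** plant one set drawing 20 members from the consensus
genes plus 10 background genes, among 40 background sets of 15-80 genes.

**Survival cohorts** use a two-point hazard model: exponential event times
with hazard `baseline_hazard` (default 0.025/month, i.e. a ~27.7-month
median in the low-expression arm, the scale of published HCC cohorts) and
`baseline_hazard × true_hr` (default 0.45) for the high-expression half;
expression is bimodal N(2, 0.4) vs N(2+gap, 0.4) with gap 4; censoring is
independent exponential with its rate solved (Brent) so the expected
censored fraction equals `censor_rate` (default 0.3). Exponential times
are the minimal model supporting a constant hazard ratio; the planted gap
makes the true grouping recoverable, which the cutoff scan should — and
does — find.

What the synthetic data does *not* emulate: probe-level intensities, batch
effects, normalization artifacts, correlated noise across studies,
scale-free interactome topology, overlapping pathway cross-talk, or
non-proportional hazards. Passing tests therefore establish the
correctness of the algorithms and the recoverability of planted structure,
not performance on real cohorts; the real-data reproduction of the
published TCGA survival numbers requires supplying that cohort (see
tests/test_acceptance.py::test_tcga_best_cutoff_reproduction).

## Problem sizes and determinism

The packaged fixture (19 studies × 1500 genes, ~8,000-edge interactome,
~650-node centrality graph, n = 364 cohort) runs end-to-end in about one
second; calibration simulations use 500 null replicates (log-rank type-I
error) and 200-1000 replicates (HR recovery), chosen to make Monte-Carlo
error small relative to the properties being checked. Pipeline runs are
deterministic byte-for-byte given identical inputs; the run report embeds
the config echo, SHA-256 input checksums, package version and seed.

## Known limitations

* Univariate survival only: no multivariate Cox with clinical covariates,
  competing risks, or interval censoring.
* The hypergeometric universe is a modeling choice; enrichment q-values
  shift with it, which is why they are reported alongside k/K/n/N.
* The vote-counting denominator ignores whether a platform measured a gene
  at all; with very heterogeneous platforms a coverage-aware denominator
  would be preferable.
* Exact betweenness is O(nm); for interactome-scale graphs (10^5 edges)
  beyond the seed-neighborhood use case, sampling-based approximations
  would be needed.
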