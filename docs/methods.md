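# Methods

## Model and assumptions

The analysis treats miRNA regulation as statistical repression: if miRNA m
targets gene g, the two expression profiles should be negatively correlated
across samples of a homogeneous condition, and a disease-associated rewiring
of that regulation shows up as a change in the correlation between
conditions. Three assumptions follow:

* expression is pre-normalized on a non-negative, RPKM-like scale, and the
  Pearson correlation of those values is a meaningful coupling measure
  (no count modelling, no partial correlation, no confounder adjustment);
* sequence-based target predictions define the candidate space — the
  pipeline never proposes an edge that no prediction source lists;
* conditions are labelled per sample (normal/tumor) and each condition has
  at least 3 samples, the minimum for a defined correlation.

The differential network ("MGDRN") keeps a candidate pair when (i) the gene
passes the fold-change gate, (ii) the pair's correlation is negative in at
least one condition, and (iii) the signed correlation difference exceeds a
threshold. An edge is *up-dysregulated* when r_tumor > r_normal, i.e. the
repression observed in normal tissue weakens or collapses in tumor — the
signature of a lost tumor-suppressive miRNA — and *down* otherwise.

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `min_sources` | 2 | prediction sources that must agree; 1 admits every single-source decoy, 3+ starves real catalogs |
| `log2fc_threshold` | 1 | strict \|log₂ FC\| gate, the conventional two-fold rule |
| `pseudocount` | 0.01 | keeps zero-expression genes finite; negligible on the RPKM scale |
| `delta_threshold` | 0.2 | strict gate on \|r_tumor − r_normal\|; below it cohort-noise differences dominate |
| `difference_mode` | `signed` | threshold the signed difference; the `magnitude` option thresholds \|·\| of each side instead, but then up/down directions are not faithful to the rewiring |
| `top_k` | 10 | length of each centrality ranking |
| `closeness_mode` | `normalized` | Wasserman–Faust closeness ((r−1)/Σd)·((r−1)/(N−1)); the raw reciprocal 1/Σd is bounded by 1/(N−1) and is incomparable across network sizes, so rankings on large networks effectively require the normalized form. Raw mode is kept for fidelity to the textbook definition |
| `alpha` | 0.05 | raw per-cell enrichment significance; Benjamini–Hochberg available via `bh_correct` but off by default, matching the common practice of screening at raw P < 0.05 |
| `min_density` | 0.8 | fraction of significant cells a bicluster must reach to be a module |

Enrichment is the exact upper-tail hypergeometric test. DAVID-style tools
use the EASE score (the same tail with the overlap deflated by one); that
variant is available via `ease=True` but the exact test is the default
because it is the standard model for over-representation under a fixed
universe. The universe defaults to catalog genes ∩ measured genes: genes
that could never have been targets are not part of the sampling frame.

## Design choices where the design was open

* **Signed vs absolute difference.** Thresholding |r_tumor − r_normal| is
  the only reading under which up/down dysregulation directions are well
  defined, so it is the default; the absolute-of-each reading exists as an
  option for comparison.
* **Edge eligibility.** A pair must be negative in *at least one* condition,
  with the other condition contributing its raw correlation. Requiring
  negativity in both would discard exactly the strongest rewiring events
  (negative → zero/positive), which are the phenomenon of interest.
* **FC filter on genes only.** The gene gate defines the network's gene
  side; miRNAs enter through their surviving targets. `filter_mirnas=True`
  additionally gates miRNAs for studies that want both sides differential.
* **Ranking miRNAs only.** Key-regulator lists are computed over miRNA
  nodes (centrality values are still computed on the full bipartite graph);
  ties break lexicographically for determinism, with an option to return
  all nodes tied at the k-th value. Before intersecting the three lists,
  -3p/-5p arm suffixes are stripped so a mature arm and its precursor name
  count as one regulator.
* **Dendrogram handling.** Rows and columns of the significance matrix are
  clustered independently (Euclidean distance, complete linkage by default;
  average available). Every dendrogram subtree is a candidate cluster —
  equivalent to scanning all cut heights — and candidate blocks are
  row-subtree × column-subtree products. Blocks above the density and size
  minima are accepted greedily by (density, cell count, ids), and a block
  overlapping an accepted module in both dimensions simultaneously is
  dropped, so modules never overlap in both dimensions. Distance, linkage
  and the density/size minima are all exposed because no single convention
  exists for calling modules off a clustered heatmap.

## Numerical notes

* Correlations are computed from centered dot products and clamped to
  [−1, 1] against round-off; a zero-variance vector raises an explicit
  "undefined correlation" error at the primitive level, and network
  construction skips such pairs with a logged count rather than imputing.
* All thresholds are strict inequalities (a pair at exactly Δ = 0.2, or a
  gene at exactly log₂ FC = 1, is excluded).
* Betweenness is normalized by (N−1)(N−2)/2; with fewer than three nodes
  all betweenness values are 0 by convention.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf(k−1, N, K, n)`
  and are validated against an exact rational-arithmetic sum in the tests.

## The synthetic generator

`mgdrn.synthetic` emulates the inputs of a paired tumor/normal cohort
study. Per miRNA, log-expression is Gaussian (sd `mirna_log_sd` = 0.4
around a uniform log-mean); each planted edge's target gene is generated as

    log g = μ_g − β_c · (log m − μ_m) + ε,   ε ~ N(0, noise_sd²),

then exponentiated. Because the pipeline correlates the *exponentiated*
values, β_c is calibrated per condition by bisection against the exact
lognormal-correlation closed form
corr(e^U, e^V) = (e^{cov(U,V)} − 1)/√((e^{var U} − 1)(e^{var V} − 1)),
so the expected sample PCC equals the configured target exactly rather than
approximately. Defaults plant r = −0.7 in both conditions for stable edges
and attenuate tumor coupling to r = −0.1 for dysregulated edges (ΔPCC 0.6,
three times the pipeline gate). With `mirna_log_sd` = 0.4 and
`noise_sd` = 0.15 the attainable correlation floor is ≈ −0.79, leaving
headroom for the −0.7 target.

The reference fixture is 200 genes × 50 miRNAs over 60+60 samples, 150
true edges (distinct target genes, so each gene has one driving miRNA and
per-edge correlation targets stay exact), 100 of them dysregulated; every
edge gene and 20 edge-free genes get a ±2 log₂-fold tumor mean shift.
Decoy design follows a small power calculation made before any tests were
run: 200 single-source decoys exercise the consensus filter at zero cost;
10 multi-source decoys (uncoupled expression) pass consensus and are
removed only by the correlation filters — at n = 60 per condition an
uncoupled pair's ΔPCC exceeds 0.2 with probability ≈ 0.25, so they
contribute ~2–3 false edges per run against ~100 true positives, and the
~50 stable edges leak ≈ 2 more, keeping expected precision ≈ 0.95. Planted
synergy modules (3 miRNAs × 12 pathways, 4 × 4) give each module miRNA 8
dysregulated targets and put 5 of them in each module pathway
(hypergeometric p ≈ 10⁻⁵ at a ~200-gene universe); background pathways
sample genes outside the module target sets. About 30 % of prediction rows
are written with the precursor spelling to exercise mature-name mapping,
and three precursors also map to an unmeasured -5p arm to exercise
one-to-many expansion.

All randomness flows through one `numpy.random.default_rng(seed)` (PCG64),
so a config + seed reproduces a dataset bit for bit across platforms.

**What the generator does not emulate:** count noise and mean–variance
coupling of real RNA-seq, library-size and batch effects, shared targets
(each synthetic gene has one driving miRNA, while real 3′-UTRs are hit by
many), correlated decoys, unbalanced cohort sizes, and pathway databases'
overlapping/nested gene sets. Passing tests therefore demonstrate that the
implementation recovers the structure it is specified to recover under its
own model — not that the thresholds are optimal for any particular real
cohort.

## Problem sizes used in verification

Oracle checks run on 100 random bipartite graphs (≤ 30 nodes), 1,000
random vector pairs, 300 sampled hypergeometric configurations (universe
≤ 200), and 20 small random end-to-end instances; recovery statistics are
medians over 20 seeded replicates of the reference fixture. These sizes
make the full suite run in seconds while keeping every check at the scale
where the brute-force oracles are exact.

## Known limitations

* Correlation thresholds carry no significance statement — no p-values or
  FDR on edges, by design.
* The bipartite convention ignores gene–gene and miRNA–miRNA co-regulation;
  betweenness/closeness are computed on the undirected graph.
* Module calling is a heuristic over dendrogram blocks; a planted module
  split early by an unlucky linkage can be reported as two sub-blocks.
* `pearson_correlation` requires n ≥ 3; condition networks refuse to build
  on fewer samples rather than degrade silently.
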