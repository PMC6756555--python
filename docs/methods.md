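# Methods

`switchnet` identifies *switch genes* in a two-group (disease vs control)
expression experiment: genes that sit inside a co-expression network yet are
predominantly **anti**-correlated with their interaction partners and
connected mainly **outside** their own community. Such nodes are hypothesized
to mark expression reprogramming between phenotypes. This note records the
model, its assumptions, the defaults, and the numerical choices where the
design was genuinely open.

## Pipeline

1. **Expression preparation.** Input is a genes × samples log2-intensity
   matrix (TSV or GEO series-matrix format) with a group label per sample.
   If any value exceeds 50 the matrix is taken to be on the linear scale and
   `log2(x+1)` is applied (override with `scale=`). Probe-level arrays are
   collapsed to one row per symbol by keeping the probe with the highest mean
   expression — the common microarray convention. Genes whose maximum
   expression across samples falls below the `floor_percentile`-th percentile
   of all matrix values (default 20) are removed as "not or only slightly
   expressed". The percentile is a pragmatic default: it trims the unexpressed
   tail without touching structured genes in the synthetic benchmark; there is
   no principled universal value, so it is configurable.

2. **Differential filter.** Per gene: group means on the log2 scale, linear
   fold-change `2^(mean_d − mean_c)`, a two-sided Welch (unequal-variance)
   t-test, and Benjamini–Hochberg FDR across genes. A gene is retained when
   `max(fc, 1/fc) ≥ fc_threshold` (default 2; both directions pass) and
   `fdr ≤ fdr_threshold` (default 0.05). Welch is used because group sizes of
   ~10 give no basis for an equal-variance assumption. Degenerate genes with
   zero variance in both groups get p = 1 when the means agree and p = 0 when
   they do not — a documented convention, not an inference.

3. **Network.** Pearson correlation between every pair of retained genes is
   computed across the **pooled** samples of both groups; pooling is what
   makes case-vs-control reprogramming visible as negative correlation. An
   edge is kept iff `|r| ≥ r_threshold`, with the *signed* weight retained;
   isolated nodes are dropped. The default threshold is data-driven: the
   99.9th percentile of |r| over 10,000 random gene pairs in which one
   profile of each pair is independently permuted (destroying co-expression,
   preserving marginals). A fixed value may be supplied instead.

4. **Communities.** k-means (Lloyd, Euclidean) on per-gene z-scored
   expression profiles of the network nodes. For each k in `k_min..k_max`
   (default 2..15) the clustering is restarted `n_replicates` times (default
   100) from random centroids and the lowest-SSE replicate kept. The
   community count is the scree elbow: the smallest k whose relative SSE drop
   to k+1 falls below 5%. The elbow is traditionally read by eye; the 5% rule
   is our deterministic stand-in and is overridable (`k_override`).

5. **Heat cartography.** With `κ_i` = edges from node *i* into its own
   community and `k_i` = total degree:
   * `Zg_i = (κ_i − mean κ) / sd κ` standardized within the community
     (population SD; `Zg = 0` for communities whose κ has zero spread — those
     nodes are by construction not local hubs);
   * `Kπ_i = 1 − (κ_i / k_i)²`, 0 when all links are internal, → 1 as links
     become external;
   * `APCC_i` = mean signed Pearson r between *i* and its neighbors (read off
     the edge weights).

   Node roles on the (Kπ, Zg) plane: the plane is split at `Zg = 2.5` and Kπ
   breakpoints {0.3, 0.6, 0.8} into R1–R7 (a Guimerà–Amaral-style partition).
   Only R4 — `Zg < 2.5`, `Kπ > 0.8` — carries meaning downstream; the other
   regions are presentation-only labels. Hub taxonomy follows the APCC sign
   and magnitude for every node: **fight-club** (`APCC < 0`), **party**
   (`APCC ≥ 0.5`), **date** (`0 ≤ APCC < 0.5`); the 0.5 boundary between
   date and party is a tuning choice (the taxonomy beyond the fight-club
   sign is not used in any computation). Separately, `Zg > 5` flags local
   hubs (`is_hub`). **Switch genes** are the nodes with `Zg < 2.5`,
   `Kπ > 0.8` and `APCC < 0`.

6. **Robustness.** The network's average shortest path (unweighted, averaged
   over connected pairs only — the statistic stays finite as the graph
   fragments; an edgeless graph scores 0) is tracked while removing, in 20
   equal batches, as many nodes as there are switch genes. Removal is by
   category (total hubs = `Zg > 5`, party / date / fight-club hubs by APCC
   class, switch genes, random) in decreasing-degree order, ties broken by
   node id for determinism. The random category averages 20 uniform draws.
   Categories smaller than the removal budget are exhausted with a logged
   truncation.

7. **Downstream.** (a) Hypergeometric upper-tail enrichment of a query list
   against GMT gene sets with BH-FDR across sets; `ease=True` subtracts one
   from the observed overlap, mimicking DAVID's conservative EASE score. The
   default universe is all genes of the platform after probe collapse.
   (b) Cross-run switch-list overlaps reported in both bookkeepings:
   exclusive intersections (UpSet semantics) and pairwise totals (Venn
   semantics). (c) TF ranking: TF→target edges are first filtered BETA-minus
   style (peak intensity < 500, regulatory potential < 1, both strict), the
   bipartite graph induced by the query genes is built, and TFs are ordered
   by degree (distinct query targets), then betweenness centrality, then
   symbol — a fully deterministic ordering.

## Reproducibility

One seed governs every stochastic stage. Per-stage substreams are derived
from `numpy.random.SeedSequence(seed)` under the fixed labels `kmeans`,
`permutation`, `random_removal`, so changing one stage's consumption cannot
perturb another's. Identical data + config + seed reproduce switch lists,
curves and tables byte for byte; the run manifest (JSON) records the config,
seed, version and per-stage counts needed to re-run.

## Synthetic data: what it emulates and what it does not

The generator draws, per module *m*, a latent factor `f_m ~ N(0,1)` per
sample, and sets

* module member: `x = baseline + loading·f_m + de·1[disease] + ε`
* switch gene (no home module): `x = baseline − swneg·Σ_m f_m − de·1[disease] + ε`
* background gene: `x = baseline + ε`, with `ε ~ N(0, noise_sd)`.

All module members carry the disease shift, so whole modules survive the
fold-change filter (the network is built only on differential genes). Switch
genes carry the shift with the opposite sign: under pooled-sample
correlation the group shift contributes `+de²/4` to every covariance, and a
same-sign shift would cancel the negative factor-loading covariance and hide
the planted anti-correlation entirely; the opposite sign makes switch genes
genuinely anti-correlated with module members (r ≈ −0.7 at the defaults)
while still passing the symmetric fold-change filter. The RNG stream is
consumed in a fixed documented order — all module factors first, then
per-gene noise row by row — so appending genes to a spec leaves earlier
genes' values untouched.

Defaults (3 modules × 60 genes, 10 switch genes, 50 background genes, 20+20
samples, `de = 2` log2 units, `loading = 0.9`, `swneg = 0.7`,
`noise_sd = 0.4`, baseline 8.0) are chosen so that within-module correlation
(~0.9) clears a permutation threshold near 0.5 with margin while between-
module correlation induced by the shared disease shift (~0.5) sits at its
edge — i.e. the recovered structure is driven by the planted modules, not by
trivially separable data.

The generator does **not** simulate probe-level artifacts, batch effects,
missing values, heavy-tailed noise, or correlated noise between modules.
Passing the planted-recovery benchmark therefore shows the pipeline
faithfully recovers the structure it is defined on — not that real
microarray data satisfies that structure.

## Problem sizes and known limitations

The benchmark runs the full pipeline on 240-gene, 40-sample datasets over
ten seeds (about 10 s per run), a size at which every stage's behavior is
exercised without approximations; all stages scale to array-sized inputs
(tens of thousands of probes) since the heavy steps are vectorized
correlation, `KMeans`, and BFS shortest paths in compiled code.

Limitations: the elbow rule can pick a larger k than planted when clusters
are small enough to split profitably; the average-shortest-path convention
(connected pairs only) makes curves non-monotone when removal disconnects
distant pairs; the low-expression floor can never remove *all* genes (the
floor percentile is bounded by the global maximum), so the "all removed"
error is defensive only; and on real accession data the unreported upstream
settings (correlation threshold, k, test choice) mean switch lists are
reproducible only approximately.
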