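# Methods

This note records the model implemented by `treede`, the meaning and
defaults of every parameter, the design of the synthetic data generator,
and the numerical and design decisions a user should know before
trusting the output.

## Data model

The unit of data is a **replicate tensor**: counts with axes
(sample, feature, inferential replicate), plus a point estimate per
(sample, feature) — by convention the replicate mean. Features are
transcripts at the leaves of a **transcript tree**; an inner node's
counts are the sum over its leaf set, taken replicate-by-replicate.
Trees may contain polytomies. Nodes carry integer IDs in post-order
(leaves first within each subtree, root last), and ancestor/descendant
queries use an Euler tour (constant-time interval containment).

## Uncertainty: inferential relative variance (infRV)

For one feature in one sample, with mean `mu` and variance `var` over
inferential replicates (sample variance, `ddof=1`):

```
infRV = max(var − mu, 0) / (mu + pc) + d
```

- `pc = 5` (pseudocount, dimensionless counts): damps the ratio for
  low-expression features.
- `d = 0.01` (global shift): the floor value; a feature whose replicate
  variance does not exceed its mean (Poisson-like, no excess
  quantification noise) sits exactly at `d`.

`mean_infrv` averages this over samples. It is computed on **unscaled**
replicate counts: infRV compares replicate variance to the replicate
mean within a sample, and normalization rescales both coherently only in
the Poisson-excess sense; keeping it on raw counts matches the
definition and keeps the threshold interpretable across datasets.
At least 2 replicates are required.

## Differential testing

- **Normalization**: median-of-ratios size factors computed from the
  leaf point estimates (geometric-mean reference over samples; if no
  feature is positive in all samples, the reference falls back to the
  features positive everywhere in a logged warning path). Node counts
  are scaled by the same per-sample factors — aggregation and scaling
  commute, so scaled inner nodes equal the aggregated scaled leaves.
- **Expression filter**: a node is tested only if at least
  `filter_min_samples = 3` samples have scaled point counts
  `>= filter_min_count = 10`. The filter runs on *normalized* counts so
  that results do not depend on per-sample library size. Filtered nodes
  get p-value 1 and statistic 0. (The absolute threshold means a global
  rescaling of every library can still move features across the filter
  boundary; the test statistic itself is rank-based and invariant.)
- **Statistic**: per replicate, the centered Mann–Whitney rank sum of
  group 2 (`ranksum − n2(n+1)/2`), averaged over replicates. Because
  mid-ranks are invariant under permutation of labels, the statistic for
  all permutations is a single matrix product between mean ranks and the
  assignment matrix.
- **Null**: permutation of sample labels. If the number of distinct
  assignments `C(n, n2)` is at most `n_permutations` (default 1000), the
  null is exhaustive and `p = count/B` with the identity permutation
  included (so `p > 0`); otherwise `B` assignments are sampled with a
  seeded generator and `p = (1 + count)/(1 + B)`. Ties against the
  observed statistic use an absolute tolerance of `1e-9`. Constant
  features get `p = 1` and are excluded from the null pool.
- **Pooling**: the null is pooled *across features within a call* (as in
  rank-based inferential-replicate testing generally), which buys
  resolution far below `1/B`. Leaves and inner nodes are tested in
  **separate calls**: inner nodes aggregate counts, and pooling them
  with leaves shifts the shared null so that inner-node p-values become
  stochastically small on null data. `test_tree(..., pooled=True)`
  exists to demonstrate exactly this pathology and is not for inference.
- **Direction**: per replicate, the log2 fold change of group means with
  pseudocount `c0 = 1`; a node is "up" ("down") if at least
  `min_p = 0.70` of replicates agree in sign, else "unsure". Zero LFCs
  count toward neither direction.
- **Significance threshold**: the Benjamini–Hochberg step-up threshold
  at nominal FDR `alpha` computed on the **tested leaf** p-values (the
  leaf universe is fixed and method-independent, so thresholds are
  comparable with plain transcript-level testing). The same numeric
  threshold is applied to inner-node p-values during selection. If
  nothing passes, the threshold is `None` and nothing is selected.

## Node selection

Top-down from the root, descending into every child whose subtree
contains at least one significant node. A significant inner node is
**selected** iff all three hold:

1. at least one child is not significant — otherwise the signal exists
   at a lower level and traversal continues;
2. all confidently-signed strict descendants share one direction
   ("unsure" descendants are ignored; vacuously true if none are
   confident) — aggregating opposite-direction children would fabricate
   a signal;
3. every child's mean infRV strictly exceeds `mirv_thresh = 0.40` —
   if some child is already stable, the data support descending to it.

Significant leaves are always selected. When a significant node is *not*
selected, traversal continues into its children, and the violated rule
is recorded in `skipped_significant`. The root itself can be selected
(with a logged warning — a root-level call usually signals a global
artifact). The result is an antichain by construction (equivalently:
the selected set equals the "eligible" nodes — significant leaves and
rule-satisfying inner nodes — that have no eligible proper ancestor; the
test suite checks this closed form against the traversal on hundreds of
random instances). Branches of the root can be processed in parallel
(`n_workers`); results are identical to the serial walk.

Limiting cases: with `mirv_thresh = +inf` rule 3 never holds and the
selection is exactly the BH-significant leaves; with everything
significant nothing above the leaves is selected (rule 1).

## Synthetic data generator

Scope: desk-scale fixtures with known truth, not a biological simulator.

- **Design**: `n_genes` genes (default 200), transcripts per gene
  uniform on `transcripts_per_gene` (default 1–5), two groups of
  `n_per_group = 6` samples. Gene classes by largest-remainder rounding
  of fractions 80% null / 10% all-transcripts-DE / 10% one-transcript-DE
  (the highest-expressed transcript). Fold changes uniform on
  `fc_range = (2, 6)` (a low-signal constant `LOW_SIGNAL_FC = (1.4, 2.8)`
  is provided), direction random; `null=True` fixes all fold changes
  at 1.
- **Counts**: negative binomial. Baseline means are log-normal
  (`mean_log = 4`, `sd_log = 1`, i.e. median ~55 counts); dispersion
  follows the decreasing trend `alpha(mu) = disp_a/mu + disp_b`
  (`1/mu + 0.01`), so high-expression features are less dispersed.
  `lib_size` scales all means.
- **Replicate uncertainty**: per sample and multi-transcript gene, a
  fraction `uncertainty` (default 0.5) of the gene's reads is declared
  ambiguous; each inferential replicate reallocates them among the
  gene's transcripts by a Dirichlet-multinomial draw centered on the
  true within-gene proportions with concentration `concentration`
  (default 10 — chosen so that leaf infRVs land in a plausible range
  rather than being uniformly extreme; 1 makes the within-gene split
  nearly uninformative). The non-ambiguous remainder is fixed by
  largest-remainder rounding; gene totals are conserved exactly in
  every replicate. The point estimate is the replicate mean.
- **Fixture tree**: greedy agglomeration — repeatedly merge the pair of
  current roots whose merged node most reduces mean infRV relative to
  the mean of the pair's own values; stop when no merge improves by more
  than `tol = 0.01`; join leftover roots under a synthetic root. Merged
  infRVs come from additive sufficient statistics (per-sample replicate
  means, variances and pairwise covariances), so the search never
  re-sums counts. Because ambiguous reallocation makes within-gene
  counts anti-correlated, this recovers within-gene groupings and
  guarantees (up to `tol`) that a parent's mean infRV does not exceed
  its children's average — the monotone-uncertainty property the
  selector relies on.

Realism limits: no GC/length bias, no correlation between genes, no
between-sample batch structure, ambiguity only *within* genes (real
multimapping also crosses gene families), and NB dispersion is a smooth
trend without gene-specific outliers. Conclusions about real data
should not be drawn from the generator; it exists to give the method a
truth-labeled workload with the uncertainty structure it targets.

## Evaluation conventions

- **Node ground truth**: true (pre-ambiguity) counts are aggregated to
  every node; a node is truly DE iff its absolute log2 ratio of group
  means strictly exceeds that of the root (the root aggregates
  everything, so its LFC is the baseline compositional drift any real
  signal must beat; the root itself is never truly DE). Ground-truth
  LFCs use no pseudocount by default (`c0 = 0`): true counts are
  noise-free, and a pseudocount would only bias small-mean nodes.
- **TPR/FDR**: only the selected node's own label counts (a selected
  inner node is one feature; its descendants are not unpacked). FDR is
  false selections over selections. TPR has two documented conventions:
  the **node universe** (truth-DE nodes among leaves plus selected inner
  nodes — the feature set the method actually ranks) and the
  **transcript coverage** universe (fraction of truly-DE transcripts
  covered by the selection). The node-universe TPR structurally
  penalizes aggregation — a selected parent counts once while its
  absorbed DE leaves stay in the denominator — so cross-method
  comparisons (tree vs leaf-only) use the coverage convention.
- **FPR sweep** (null designs): tree FPR = selections over (tested
  leaves + selected inner nodes); leaf FPR = fraction of tested leaves
  with `p <= t`.
- **Unique branches**: nodes of one method's output with no identical,
  ancestral, or descendant node in the other's; the LFC filter curve
  recomputes FDR on unique nodes passing an observed-|LFC| cutoff.

## Numerical choices

- Sample variance uses `ddof = 1` throughout (infRV, tree building).
- Permutation p-values are never 0 (identity inclusion / add-one rule).
- BH threshold is returned as an explicit number (or `None`), not a
  reject vector, so one threshold can be applied across strata.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; a whole simulated experiment is a single
  seeded chain and is bit-reproducible.
- Tie comparisons against the permutation null use `1e-9` absolute
  tolerance to make exhaustive-null p-values robust to float summation
  order.

## Limitations

- Two-group comparisons only; no covariates, batch terms, or paired
  designs.
- The permutation test needs enough samples for a usable null
  (6 vs 6 gives 924 distinct assignments; very small designs will have
  coarse p-values even with pooling).
- The BH threshold is computed on leaves and applied to inner nodes;
  this matches the fixed-universe design but means inner-node FDR is
  controlled empirically (verified on simulations), not by the BH
  theorem directly.
- Selection quality depends on the tree: if grouping does not track
  quantification uncertainty, rule 3 rarely fires and the method
  degrades to leaf-level BH (by design).
- The infRV threshold `mirv_thresh = 0.40` is a data-scale-dependent
  default; datasets with globally low replicate noise may need a lower
  value for inner nodes to qualify.
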