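# treede

Differential expression testing over transcript trees that encode
quantification uncertainty.

## Why

Transcript-level RNA-seq quantification is uncertain wherever transcripts
share sequence: reads that map equally well to several isoforms are split
among them, and repeated re-estimation (inferential replicates from
bootstrap or Gibbs sampling) shows the split swinging from replicate to
replicate. Testing each transcript in isolation then loses real signal —
a gene-level fold change spread across two interchangeable isoforms can
leave *neither* isoform significant. But the ambiguity is structured:
counts reallocated between similar transcripts are anti-correlated, so
their **sum** is stable. A tree whose inner nodes group sequence-similar
transcripts therefore has uncertainty that decreases toward the root, and
somewhere between leaf and root there is a resolution at which the signal
is both testable and as specific as the data allow.

`treede` finds that resolution per branch, data-driven:

1. **Quantify uncertainty** per node with the inferential relative
   variance (infRV): `max(var − mean, 0)/(mean + pc) + d` averaged over
   samples, computed on the replicate counts (defaults `pc = 5`,
   `d = 0.01`; an all-stable node sits at the floor `d`).
2. **Test every node** (transcripts and inner nodes) for two-group
   differential expression with a permutation-calibrated rank statistic
   on median-of-ratios-scaled counts, averaged over inferential
   replicates. Leaves and inner nodes are tested against *separate*
   permutation null pools — pooling them makes inner-node p-values
   spuriously small (they aggregate counts and shift the shared null),
   which the test suite demonstrates.
3. **Select nodes top-down** from the root into every branch containing
   a significant node. A significant inner node is reported iff
   (a) at least one of its children is *not* significant (otherwise the
   signal already exists at a lower level), (b) all confidently-signed
   descendants change in the same direction, and (c) every child's mean
   infRV exceeds a threshold (default 0.40) — i.e. descending further
   would land on genuinely uncertain features. Significant leaves are
   always reported. The output is an antichain: no reported node is an
   ancestor of another, so each transcript is covered at most once.

The per-node significance cut is the Benjamini–Hochberg step-up threshold
computed on the tested leaf p-values at the nominal FDR (default grid
0.01/0.05/0.1), applied to leaves and inner nodes alike.

The package also ships a synthetic data generator (negative-binomial
counts with a mean-dispersion trend, Dirichlet-multinomial within-gene
count reallocation as replicate uncertainty, and an
uncertainty-agglomerated fixture tree), plus evaluation tools
(node-level ground truth, TPR/FDR, null FPR sweeps, unique-branch
comparison between methods, LFC filtering curves).

## Worked example (library)

```python
import treede as td

design = td.SimDesign(n_genes=100, n_replicates=30, seed=42)
truth, counts, tensor, tree, cond = td.simulate_experiment(design)
print(f"{tensor.n_features} transcripts, {tree.n_nodes} tree nodes, "
      f"{len(truth.de_transcripts)} truly DE transcripts")

stats = td.test_tree(tensor, tree, cond,
                     config=td.TestConfig(n_permutations=500, seed=7))
result = td.select_over_grid(tree, stats, alphas=(0.05,))[0.05]
print(f"selected {len(result.selected)} nodes at alpha=0.05 "
      f"(p-value threshold {result.pthresh:.4g})")
for v in result.selected[:5]:
    members = sorted(tree.leaf_set(v))
    print(f"  {tree.names[v]:>5}  {result.reason[v]:<16} "
          f"covers {','.join(members)}")

node_truth = td.node_ground_truth(counts, tree, cond)
tpr, fdr = td.tpr_fdr(result.selected, node_truth, tree)
print(f"TPR={tpr:.3f} FDR={fdr:.3f} against simulation ground truth")
```

Output:

```text
301 transcripts, 522 tree nodes, 44 truly DE transcripts
selected 43 nodes at alpha=0.05 (p-value threshold 0.005426)
   t145  significant_leaf covers t145
    N38  criteria_met     covers t121,t122,t124
   t214  significant_leaf covers t214
   t215  significant_leaf covers t215
   t216  significant_leaf covers t216
TPR=0.218 FDR=0.000 against simulation ground truth
```

Node `N38` is the typical win: three transcripts of one gene whose
individual counts swing between replicates, reported once as a stable
group. The TPR here uses the node-universe convention (DE leaves that
were absorbed into a selected group still count in the denominator);
`td.tpr_fdr(..., universe="transcripts")` gives the coverage convention
(fraction of truly-DE transcripts covered by the selection), which is
the right scale for comparing against leaf-only testing.

## Worked example (CLI)

```sh
$ treede simulate --out demo/sim --genes 60 --replicates 20 --seed 5
wrote synthetic experiment to demo/sim
$ treede test --tree demo/sim/tree.nwk --replicates demo/sim/replicates \
    --condition demo/sim/condition.tsv --out demo/stats.tsv \
    --permutations 300 --seed 1
wrote node statistics to demo/stats.tsv
$ treede select --tree demo/sim/tree.nwk --stats demo/stats.tsv \
    --out demo/sel --alpha 0.05
alpha=0.05: 22 node(s) -> demo/sel/selected_alpha0.05.tsv
$ head -4 demo/sel/selected_alpha0.05.tsv
node	reason	height	n_transcripts	transcripts
t114	significant_leaf	0	1	t114
t115	significant_leaf	0	1	t115
t118	significant_leaf	0	1	t118
```

`treede evaluate` scores a selection against the simulation truth and can
compare two methods' node sets (`--compare`). Every subcommand accepts a
flat `key=value` `--config` file; flags override config values. File
formats (newick trees, feature-major count TSVs, per-replicate TSV
directories or a single HDF5 container, two-column condition TSVs) are
documented in `treede/io.py` and auto-detected where applicable.

## Reproduction

All results are deterministic given the seed. To reproduce the analytic
reference value shipped with the repository:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which recomputes the default-parameter infRV for a feature with
replicate mean 10 and variance 8 (variance below the mean clamps the
excess-variance term, leaving exactly the global shift 0.01) and writes
`{"t1": {"value": 0.01, "n": 1}}`.

The statistical guarantees — selector equivalence with a brute-force
reference, the antichain invariant, leaf-limit equivalence, null
calibration with FPR agreement, the pooled-null pathology, signal
recovery versus leaf-level BH, and the masked-gene rescue — are pinned in
`tests/test_acceptance.py` and run as part of the ordinary test suite.

See `docs/methods.md` for the model, parameter semantics, generator
design, and known limitations.
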