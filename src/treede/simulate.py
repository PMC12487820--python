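"""Synthetic two-group RNA-seq experiments with quantification uncertainty.

The generator produces, at desk scale, everything the tree-based testing
workflow consumes: a gene/transcript design with known fold changes, a
negative-binomial count matrix, inferential replicates whose disagreement
mimics within-gene read ambiguity (multimapping between sequence-similar
isoforms), and a transcript tree built so that uncertainty decreases
toward the root.

Design conventions: two groups of ``n_per_group`` samples (default 6 vs 6);
80% of genes null, 10% with every transcript differentially expressed at a
shared fold change, 10% with exactly one expressed transcript differentially
expressed; fold changes drawn uniformly from ``fc_range`` (default [2, 6];
a low-signal variant uses [1.4, 2.8]) with a random up/down direction.  The
null variant fixes every fold change at 1.

Replicate uncertainty is injected at the count level: per sample and gene,
a fraction ``uncertainty`` of the gene's reads is ambiguous and is
re-allocated among the gene's transcripts by a fresh Dirichlet-multinomial
draw in each inferential replicate, conserving the gene total.  Individual
transcripts of an ambiguous gene therefore show large inferential relative
variance while their within-gene aggregate shows almost none — the regime
the tree method exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import ReplicateTensor, TranscriptTree, from_nested, unify_forest
from .uncertainty import InfRVParams

logger = logging.getLogger("treede")


@dataclass(frozen=True)
class SimDesign:
    """Parameters of a synthetic two-group experiment.

    ``transcripts_per_gene`` is an inclusive integer range sampled
    uniformly.  ``disp_a``/``disp_b`` parameterize the mean-dispersion
    trend ``alpha(mu) = disp_a/mu + disp_b`` of the negative-binomial
    counts.  ``uncertainty`` is the fraction of each gene's reads that is
    ambiguous between its transcripts; ``concentration`` scales the
    Dirichlet used to re-allocate those reads per inferential replicate
    (smaller = wilder swings).  ``null=True`` forces every fold change
    to 1.
    """

    n_genes: int = 200
    n_per_group: int = 6
    transcripts_per_gene: tuple = (1, 5)
    frac_null: float = 0.8
    frac_all_de: float = 0.1
    frac_one_de: float = 0.1
    fc_range: tuple = (2.0, 6.0)
    null: bool = False
    mean_log: float = 4.0
    sd_log: float = 1.0
    disp_a: float = 1.0
    disp_b: float = 0.01
    n_replicates: int = 100
    uncertainty: float = 0.5
    concentration: float = 10.0
    lib_size: float = 1.0
    seed: int = 0

    def __post_init__(self):
        total = self.frac_null + self.frac_all_de + self.frac_one_de
        if abs(total - 1.0) > 1e-9:
            raise ValueError("gene-class fractions must sum to 1")
        if not self.null and self.fc_range[0] <= 1.0:
            raise ValueError("fc_range low bound must exceed 1 for signal designs")
        if not (0.0 <= self.uncertainty <= 1.0):
            raise ValueError("uncertainty must lie in [0, 1]")
        lo, hi = self.transcripts_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("transcripts_per_gene must be a valid integer range")


LOW_SIGNAL_FC = (1.4, 2.8)


@dataclass
class SimTruth:
    """Ground truth of a synthetic design.

    ``transcripts`` is a DataFrame indexed by transcript ID with columns
    ``gene``, ``fold_change``, ``de`` (bool) and ``baseline_mean`` (the
    group-1 expected count).  ``genes`` maps gene ID to its class
    ('null', 'all_de', 'one_de'); ``gene_map`` maps gene ID to its
    transcript IDs.
    """

    transcripts: pd.DataFrame
    genes: dict
    gene_map: dict = field(default_factory=dict)

    @property
    def de_transcripts(self) -> list:
        return list(self.transcripts.index[self.transcripts["de"]])


def _largest_remainder(n: int, fractions) -> list:
    """Integer class sizes summing to n, by largest-remainder rounding."""
    raw = [n * f for f in fractions]
    base = [int(np.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def make_design(design: SimDesign, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw gene classes, transcript structure, baselines and fold changes."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    n = design.n_genes
    sizes = _largest_remainder(
        n, (design.frac_null, design.frac_all_de, design.frac_one_de)
    )
    classes = (["null"] * sizes[0] + ["all_de"] * sizes[1] + ["one_de"] * sizes[2])
    rng.shuffle(classes)

    lo, hi = design.transcripts_per_gene
    n_txps = rng.integers(lo, hi + 1, size=n)

    rows = []
    genes = {}
    gene_map = {}
    width = len(str(n))
    t_total = int(n_txps.sum())
    t_width = len(str(t_total))
    t_idx = 0
    for g in range(n):
        gene = f"g{g + 1:0{width}d}"
        genes[gene] = classes[g]
        txps = []
        base = np.exp(rng.normal(design.mean_log, design.sd_log, size=int(n_txps[g])))
        fc = np.ones(int(n_txps[g]))
        if not design.null and classes[g] != "null":
            mag = rng.uniform(design.fc_range[0], design.fc_range[1])
            f = mag if rng.random() < 0.5 else 1.0 / mag
            if classes[g] == "all_de":
                fc[:] = f  # every transcript of the gene shares one fold change
            else:
                fc[int(np.argmax(base))] = f  # the highest-expressed transcript
        for k in range(int(n_txps[g])):
            t_idx += 1
            tid = f"t{t_idx:0{t_width}d}"
            txps.append(tid)
            rows.append((tid, gene, float(base[k]), float(fc[k]), fc[k] != 1.0))
        gene_map[gene] = txps

    df = pd.DataFrame(
        rows, columns=["transcript", "gene", "baseline_mean", "fold_change", "de"]
    ).set_index("transcript")
    logger.debug(
        "design: %d genes (%s), %d transcripts, %d DE",
        n, dict(zip(("null", "all_de", "one_de"), sizes)), len(df), df["de"].sum(),
    )
    return SimTruth(transcripts=df, genes=genes, gene_map=gene_map)


def condition_labels(design: SimDesign) -> np.ndarray:
    """The two-group condition vector matching ``simulate_counts`` rows."""
    return np.array(
        ["c1"] * design.n_per_group + ["c2"] * design.n_per_group, dtype=object
    )


def sample_ids(design: SimDesign) -> list:
    return [f"s{i + 1:02d}" for i in range(2 * design.n_per_group)]


def simulate_counts(
    truth: SimTruth, design: SimDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Negative-binomial count matrix (samples x transcripts).

    Group-1 means are the design baselines; group-2 means are multiplied by
    the true fold change.  The dispersion follows the mean-dispersion trend
    ``disp_a/mu + disp_b``; ``lib_size`` multiplies every mean.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed + 1)
    base = truth.transcripts["baseline_mean"].to_numpy()
    fc = truth.transcripts["fold_change"].to_numpy()
    s = 2 * design.n_per_group
    mu = np.tile(base, (s, 1)) * design.lib_size
    mu[design.n_per_group:, :] *= fc
    disp = design.disp_a / mu + design.disp_b
    r = 1.0 / disp
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)
    return pd.DataFrame(
        counts.astype(np.float64),
        index=sample_ids(design),
        columns=list(truth.transcripts.index),
    )


def simulate_replicates(
    true_counts: pd.DataFrame,
    gene_map: dict,
    uncertainty: float,
    design: SimDesign,
    rng: np.random.Generator | None = None,
) -> ReplicateTensor:
    """Inferential replicates with within-gene count ambiguity.

    For each sample and multi-transcript gene, a fraction ``uncertainty``
    of the gene's reads is re-allocated among its transcripts by a
    Dirichlet-multinomial draw per replicate (Dirichlet centered on the
    true within-gene proportions, concentration ``design.concentration``);
    the remaining reads stay fixed.  Gene totals are conserved in every
    replicate.  The tensor's point estimate is the replicate mean.
    """
    if not (0.0 <= uncertainty <= 1.0):
        raise ValueError("uncertainty must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(design.seed + 2)
    x = true_counts.to_numpy(dtype=np.float64)
    s, f = x.shape
    r = design.n_replicates
    col = {t: j for j, t in enumerate(true_counts.columns)}
    counts = np.repeat(x[:, :, None], r, axis=2)

    for gene, txps in gene_map.items():
        cols = [col[t] for t in txps if t in col]
        if len(cols) < 2 or uncertainty == 0.0:
            continue
        sub = x[:, cols]  # (samples, T)
        for m in range(s):
            c = sub[m]
            total = c.sum()
            if total <= 0:
                continue
            ambiguous = int(round(uncertainty * total))
            if ambiguous == 0:
                continue
            pi = c / total
            # fixed share per transcript; remainder goes to the ambiguous pool
            fixed = np.floor(c * (1.0 - uncertainty)).astype(np.int64)
            spare = int(total - ambiguous - fixed.sum())
            if spare > 0:  # distribute rounding remainder by largest share
                order = np.argsort(-(c * (1.0 - uncertainty) - fixed))
                for i in order[:spare]:
                    fixed[i] += 1
            elif spare < 0:
                order = np.argsort(-fixed)
                left = -spare
                for i in order:
                    take = min(left, int(fixed[i]))
                    fixed[i] -= take
                    left -= take
                    if left == 0:
                        break
            alpha = design.concentration * pi + 1e-6
            props = rng.dirichlet(alpha, size=r)  # (replicates, T)
            draws = rng.multinomial(ambiguous, props)  # (replicates, T)
            counts[m, cols, :] = fixed[:, None] + draws.T

    return ReplicateTensor.from_replicates(
        counts, list(true_counts.columns), list(true_counts.index)
    )


# ---------------------------------------------------------------------------
# fixture tree construction
# ---------------------------------------------------------------------------


def build_fixture_tree(
    tensor: ReplicateTensor,
    transcripts=None,
    params: InfRVParams = InfRVParams(),
    tol: float = 0.01,
) -> TranscriptTree:
    """Greedy uncertainty-reducing agglomeration of transcripts into a tree.

    Repeatedly merges the pair of current roots whose aggregate most
    reduces mean infRV relative to the average of the pair's own values,
    stopping when no merge reduces it by more than ``tol``; the remaining
    roots are joined under a synthetic root.  On ambiguity-injected data
    this recovers within-gene groupings (anti-correlated replicate counts
    cancel on aggregation), giving trees whose uncertainty decreases
    toward the root.

    Merged infRVs are computed from per-sample replicate means, variances
    and covariances, which are all additive under aggregation — no counts
    are re-summed during the search.
    """
    if tensor.n_features < 2:
        raise ValueError("need at least 2 transcripts to build a tree")
    transcripts = list(transcripts) if transcripts is not None else list(tensor.feature_ids)

    x = tensor.counts  # (S, F, R)
    s, f, r = x.shape
    mu = x.mean(axis=2).T.copy()  # (F, S)
    xc = x - x.mean(axis=2, keepdims=True)
    # per-sample covariance over replicates between all feature pairs
    cov = np.einsum("sir,sjr->ijs", xc, xc) / (r - 1)  # (F, F, S)
    var = np.einsum("iis->is", cov).copy()  # (F, S)

    def mirv_of(mu_, var_):
        return (np.maximum(var_ - mu_, 0.0) / (mu_ + params.pc) + params.d).mean(axis=-1)

    node_mirv = mirv_of(mu, var)  # (F,)
    active = np.ones(f, dtype=bool)
    structure: list = list(tensor.feature_ids)

    def pair_reduction(i, js):
        """Reduction in mean infRV when merging node i with each j."""
        m = mu[i] + mu[js]  # (J, S)
        v = var[i] + var[js] + 2.0 * cov[i, js, :]
        merged = mirv_of(m, v)
        return 0.5 * (node_mirv[i] + node_mirv[js]) - merged, merged

    # reduction matrix over active pairs
    red = np.full((f, f), -np.inf)
    merged_mirv = np.zeros((f, f))
    idx = np.arange(f)
    for i in range(f):
        js = idx[i + 1:]
        if js.size:
            red[i, js], merged_mirv[i, js] = pair_reduction(i, js)

    while active.sum() > 1:
        flat = np.argmax(red)
        i, j = np.unravel_index(flat, red.shape)
        if red[i, j] <= tol:
            break
        # merge j into i
        mu[i] += mu[j]
        var[i] = var[i] + var[j] + 2.0 * cov[i, j, :]
        cov[i, :, :] += cov[j, :, :]
        cov[:, i, :] += cov[:, j, :]
        node_mirv[i] = merged_mirv[i, j]
        structure[i] = (structure[i], structure[j])
        active[j] = False
        red[j, :] = -np.inf
        red[:, j] = -np.inf
        others = idx[active & (idx != i)]
        if others.size:
            reductions, merged = pair_reduction(i, others)
            lo = others[others < i]
            hi = others[others > i]
            red[lo, i], merged_mirv[lo, i] = (
                reductions[others < i], merged[others < i]
            )
            red[i, hi], merged_mirv[i, hi] = (
                reductions[others > i], merged[others > i]
            )
        red[i, i] = -np.inf

    roots = [structure[i] for i in idx[active]]
    trees = [from_nested(rt) for rt in roots if not isinstance(rt, str)]
    logger.debug("fixture tree: %d merges, %d root(s)", f - int(active.sum()), len(roots))
    return unify_forest(trees, transcripts)


def simulate_experiment(design: SimDesign):
    """End-to-end generator: truth, counts, replicates, tree, condition.

    One seed drives the whole chain; returns
    ``(truth, counts, tensor, tree, condition)``.
    """
    rng = np.random.default_rng(design.seed)
    truth = make_design(design, rng)
    counts = simulate_counts(truth, design, rng)
    tensor = simulate_replicates(counts, truth.gene_map, design.uncertainty, design, rng)
    tree = build_fixture_tree(tensor, list(counts.columns))
    return truth, counts, tensor, tree, condition_labels(design)
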