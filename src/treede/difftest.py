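"""Two-group differential testing of tree nodes with inferential replicates.

The reference test mirrors the statistic used by uncertainty-aware
two-group testing on inferential replicates: per replicate, a centered
Mann-Whitney rank statistic between the two condition groups; averaged
over replicates into a single statistic ``z`` per feature.  Significance
comes from a permutation null — condition labels are permuted (exhaustively
when the number of distinct assignments is small enough, otherwise by
seeded sampling) and the permuted statistics of *all features in the call*
are pooled into one empirical null, against which each feature's |z| is
compared.  Pooling the null across features is what makes it matter
whether leaves and inner nodes are tested together or separately: inner
nodes aggregate away replicate disagreement, so their rank statistics are
less shrunken toward zero, and testing everything in one pool hands the
inner nodes systematically smaller p-values.  ``test_tree`` therefore runs
the test once on the leaves and once on the inner nodes, with two
independent nulls.

Counts are normalized by median-of-ratios size factors computed on the
leaves only (inner-node counts are sums of leaf counts, so dividing by the
leaf size factor keeps aggregation linear).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .tree import ReplicateTensor, TranscriptTree
from .uncertainty import (
    InfRVParams,
    _condition_masks,
    mean_infrv,
    replicate_lfc,
    sign_directions,
)

logger = logging.getLogger("treede")

_TIE_TOL = 1e-9  # rank-sum spacing is >= 1/(2R); float slack far below that


@dataclass(frozen=True)
class TestConfig:
    """Knobs of the rank/permutation test.

    ``n_permutations`` caps the number of label assignments; when the number
    of distinct assignments does not exceed it, all of them are enumerated
    and the p-values are exact.  ``filter_min_count``/``filter_min_samples``
    define the expression filter: a feature is tested only if at least
    ``filter_min_samples`` samples have a (normalized, point-estimate) count
    of at least ``filter_min_count``.
    """

    n_permutations: int = 1000
    seed: int = 0
    two_sided: bool = True
    filter_min_count: float = 10.0
    filter_min_samples: int = 3

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not self.two_sided:
            raise ValueError("only the two-sided test is provided")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def size_factors(point_counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors from a (samples, features) count matrix.

    Features with a nonpositive geometric mean across samples are dropped
    from the median; if no feature has all-positive counts, the geometric
    mean is taken over each feature's positive entries instead (with a
    logged warning), so sparse data still normalizes.
    """
    x = np.asarray(point_counts, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("point_counts must be (samples, features)")
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    all_pos = np.isfinite(logx).all(axis=0)
    if all_pos.any():
        log_gm = logx[:, all_pos].mean(axis=0)
        ratios = logx[:, all_pos] - log_gm
    else:
        logger.warning(
            "no feature has positive counts in every sample; "
            "falling back to positive-subset geometric means"
        )
        npos = np.isfinite(logx).sum(axis=0)
        usable = npos >= 1
        if not usable.any():
            raise ValueError("all counts are zero; size factors undefined")
        log_gm = np.where(
            usable, np.nansum(np.where(np.isfinite(logx), logx, np.nan), axis=0)
            / np.maximum(npos, 1), np.nan
        )
        ratios = logx[:, usable] - log_gm[usable]
    sf = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan), axis=1))
    if np.any(~np.isfinite(sf)) or np.any(sf <= 0):
        raise ValueError("degenerate size factors; check the count matrix")
    return sf


def median_ratio_scale(
    tensor: ReplicateTensor, tree: TranscriptTree | None = None
) -> tuple[ReplicateTensor, np.ndarray]:
    """Scale a tensor by leaf-only median-of-ratios size factors.

    If ``tree`` is given and the tensor covers all tree nodes, size factors
    are computed from the leaf columns only and applied to every node (the
    supported workflow); otherwise all tensor features are treated as leaves.
    """
    if tree is not None and list(tensor.feature_ids) == list(tree.names):
        leaf_cols = tree.leaves
    else:
        leaf_cols = np.arange(tensor.n_features)
    sf = size_factors(tensor.point[:, leaf_cols])
    return tensor.scaled(sf), sf


# ---------------------------------------------------------------------------
# rank/permutation test
# ---------------------------------------------------------------------------


def _assignments(n: int, n2: int, n_permutations: int, seed: int, obs_mask: np.ndarray):
    """0/1 group-2 indicator matrix (samples x B) plus exhaustive flag."""
    total = math.comb(n, n2)
    if total <= n_permutations:
        cols = np.zeros((n, total), dtype=np.float64)
        for b, idx in enumerate(combinations(range(n), n2)):
            cols[list(idx), b] = 1.0
        return cols, True
    rng = np.random.default_rng(seed)
    cols = np.empty((n, n_permutations), dtype=np.float64)
    base = obs_mask.astype(np.float64)
    for b in range(n_permutations):
        cols[:, b] = base[rng.permutation(n)]
    return cols, False


def rank_perm_test(
    values: np.ndarray,
    condition,
    config: TestConfig = TestConfig(),
    levels=None,
) -> pd.DataFrame:
    """Replicate-averaged Mann-Whitney test with a pooled permutation null.

    Parameters
    ----------
    values : ndarray (samples, features, replicates)
        Scaled counts of the features to test together.  All features in
        one call share one permutation null (pass leaves and inner nodes
        in separate calls).

    Returns
    -------
    DataFrame with columns ``stat`` (replicate-averaged centered rank
    statistic) and ``pvalue``.  Features constant across samples in every
    replicate get ``pvalue = 1`` by convention and do not contribute to
    the pooled null.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError("values must be (samples, features, replicates)")
    n, f, r = values.shape
    _, m1, m2 = _condition_masks(condition, levels=levels)
    if m1.size != n:
        raise ValueError("condition length does not match number of samples")
    n2 = int(m2.sum())

    if f == 0:
        return pd.DataFrame({"stat": [], "pvalue": []})

    constant = (values == values[:1]).all(axis=(0, 2))

    # ranks across samples never change under label permutation, so the
    # whole permutation sweep is one matrix product on replicate-mean ranks
    ranks = rankdata(values, axis=0)
    mean_ranks = ranks.mean(axis=2)  # (samples, features)
    center = n2 * (n + 1) / 2.0
    z_obs = mean_ranks.T @ m2.astype(np.float64) - center  # (features,)

    G, exhaustive = _assignments(n, n2, config.n_permutations, config.seed, m2)
    Z = mean_ranks.T @ G - center  # (features, B)
    b = G.shape[1]

    null = np.abs(Z[~constant]).ravel()
    null.sort()
    n_null = null.size
    # count of null draws with |z_perm| >= |z_obs| (tiny slack absorbs
    # floating-point noise in identical rank sums)
    idx = np.searchsorted(null, np.abs(z_obs) - _TIE_TOL, side="left")
    count = n_null - idx
    if exhaustive:
        # the identity assignment is among the enumerated ones, so p > 0
        pvals = count / max(n_null, 1)
    else:
        pvals = (1.0 + count) / (1.0 + n_null)
    pvals = np.minimum(pvals, 1.0)
    pvals[constant] = 1.0
    z_obs[constant] = 0.0
    logger.debug(
        "rank_perm_test: %d features, %d %s assignments",
        f, b, "exhaustive" if exhaustive else "sampled",
    )
    return pd.DataFrame({"stat": z_obs, "pvalue": pvals})


# ---------------------------------------------------------------------------
# whole-tree testing
# ---------------------------------------------------------------------------


def expression_filter(point_counts: np.ndarray, config: TestConfig) -> np.ndarray:
    """Boolean mask of features passing the minimum-expression filter."""
    x = np.asarray(point_counts)
    return (x >= config.filter_min_count).sum(axis=0) >= config.filter_min_samples


def test_tree(
    tensor: ReplicateTensor,
    tree: TranscriptTree,
    condition,
    config: TestConfig = TestConfig(),
    min_p: float = 0.70,
    infrv_params: InfRVParams = InfRVParams(),
    levels=None,
    lfc_c0: float = 1.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-node statistics table for a leaf-level replicate tensor.

    Aggregates the tensor to every tree node, normalizes by leaf-only
    median-of-ratios size factors, applies the expression filter, and runs
    the rank/permutation test separately on the (tested) leaves and inner
    nodes.  ``pooled=True`` instead tests all nodes against one shared
    null — provided for diagnosing the miscalibration this causes, not for
    analysis.

    Returns a DataFrame indexed by node ID with columns ``node`` (name),
    ``is_leaf``, ``height``, ``pvalue``, ``stat``, ``lfc`` (observed
    point-estimate log2 fold change), ``mean_infrv`` (on raw counts),
    ``direction`` and ``filtered``.  Filtered nodes carry ``pvalue = 1``.
    """
    node_tensor = tensor.aggregate(tree)
    scaled, sf = median_ratio_scale(node_tensor, tree)
    logger.debug("size factors: %s", np.round(sf, 3))

    n_nodes = tree.n_nodes
    # filter on normalized counts so results are invariant to library size
    keep = expression_filter(scaled.point, config)
    leaf_mask = np.zeros(n_nodes, dtype=bool)
    leaf_mask[tree.leaves] = True

    pvalue = np.ones(n_nodes)
    stat = np.zeros(n_nodes)
    if pooled:
        groups = [np.flatnonzero(keep)]
    else:
        groups = [
            np.flatnonzero(keep & leaf_mask),
            np.flatnonzero(keep & ~leaf_mask),
        ]
    for cols in groups:
        if cols.size == 0:
            continue
        res = rank_perm_test(
            scaled.counts[:, cols, :], condition, config=config, levels=levels
        )
        pvalue[cols] = res["pvalue"].to_numpy()
        stat[cols] = res["stat"].to_numpy()

    mirv = mean_infrv(node_tensor, params=infrv_params)
    direction = sign_directions(
        scaled.counts, condition, min_p=min_p, c0=lfc_c0, levels=levels
    )
    lfc = replicate_lfc(
        scaled.point[:, :, None], condition, c0=lfc_c0, levels=levels
    )[:, 0]

    return pd.DataFrame(
        {
            "node": list(tree.names),
            "is_leaf": leaf_mask,
            "height": tree.heights(),
            "pvalue": pvalue,
            "stat": stat,
            "lfc": lfc,
            "mean_infrv": mirv,
            "direction": direction,
            "filtered": ~keep,
        }
    )


def bh_leaf_threshold(leaf_pvalues, alpha: float):
    """Benjamini-Hochberg step-up threshold on leaf p-values.

    Returns the largest order statistic ``p_(k)`` with ``p_(k) <= k*alpha/m``
    — the p-value cutoff below which a node (leaf or inner) is deemed
    significant — or ``None`` when BH rejects nothing.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    p = np.asarray(leaf_pvalues, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    ps = np.sort(p)
    m = ps.size
    crit = alpha * np.arange(1, m + 1) / m
    ok = np.flatnonzero(ps <= crit)
    if ok.size == 0:
        return None
    return float(ps[ok[-1]])
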