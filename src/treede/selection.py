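"""Top-down selection of differentially expressed tree nodes.

Given per-node p-values, mean inferential relative variance and directional
calls, the selector walks the tree from the root, descending only into
branches that contain at least one significant node.  A node is significant
when its p-value is at or below ``pthresh``, the Benjamini-Hochberg cutoff
derived on the leaves at nominal FDR ``alpha``.  When the walk reaches a
significant inner node it checks three criteria:

1. at least one of its children is nonsignificant (otherwise the signal
   already exists at a finer resolution and aggregation adds nothing);
2. every descendant with a confident directional call changes in the same
   direction (vacuously true when no descendant is confident);
3. every child's mean infRV exceeds ``mirv_thresh`` (children below the
   cutoff are quantified confidently enough to be tested on their own).

If all three hold the node is selected and the walk stops on that branch;
otherwise it continues into the children.  A significant leaf is always
selected.  The output is an antichain: no selected node is an ancestor or
descendant of another, so no transcript is counted twice.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .difftest import bh_leaf_threshold
from .tree import TranscriptTree
from .uncertainty import DOWN, UP

logger = logging.getLogger("treede")

REASON_LEAF = "significant_leaf"
REASON_CRITERIA = "criteria_met"


@dataclass(frozen=True)
class SelectionParams:
    """Tuning knobs of the node selector.

    ``alpha`` is the nominal leaf-level FDR fed to Benjamini-Hochberg;
    ``min_p`` the fraction of inferential replicates that must agree before
    a node gets a confident direction; ``mirv_thresh`` the mean-infRV cutoff
    of criterion 3.
    """

    alpha: float = 0.05
    min_p: float = 0.70
    mirv_thresh: float = 0.40

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.5 < self.min_p <= 1.0):
            raise ValueError("min_p must lie in (0.5, 1]")
        if self.mirv_thresh < 0:
            raise ValueError("mirv_thresh must be >= 0")


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    ``selected`` holds node IDs (an antichain); ``reason`` records, per
    selected node, whether it was taken as a significant leaf or as an
    inner node meeting all three criteria; ``skipped_significant`` maps
    significant inner nodes that the walk descended past to the first
    criterion (1, 2 or 3) they violated.
    """

    selected: list
    reason: dict
    skipped_significant: dict
    pthresh: float | None
    params: SelectionParams
    names: dict = field(default_factory=dict)

    @property
    def selected_names(self) -> list:
        return [self.names.get(v, str(v)) for v in self.selected]


def _validate_stats(tree: TranscriptTree, stats: pd.DataFrame) -> None:
    needed = {"pvalue", "mean_infrv", "direction"}
    missing_cols = needed - set(stats.columns)
    if missing_cols:
        raise ValueError(f"stats table missing columns: {sorted(missing_cols)}")
    if len(stats) != tree.n_nodes or not np.array_equal(
        np.asarray(stats.index), np.arange(tree.n_nodes)
    ):
        raise ValueError(
            "stats must have one row per tree node, indexed by node ID 0..N-1"
        )


def select_nodes(
    tree: TranscriptTree,
    stats: pd.DataFrame,
    pthresh: float | None,
    params: SelectionParams = SelectionParams(),
    n_workers: int = 1,
) -> SelectionResult:
    """Run the top-down selection and return the selected antichain.

    ``stats`` is the table produced by :func:`treede.difftest.test_tree`
    (or supplied externally: any per-node ``pvalue``, ``mean_infrv`` and
    ``direction`` columns indexed by node ID).  ``pthresh=None`` — the BH
    sentinel for "nothing significant anywhere" — yields an empty result.
    ``n_workers > 1`` walks the root's branches in a thread pool; the
    output is identical to the serial walk.
    """
    _validate_stats(tree, stats)
    result = SelectionResult(
        selected=[], reason={}, skipped_significant={},
        pthresh=pthresh, params=params,
        names={i: tree.names[i] for i in range(tree.n_nodes)},
    )
    if pthresh is None:
        return result

    pvalue = stats["pvalue"].to_numpy(dtype=np.float64)
    mirv = stats["mean_infrv"].to_numpy(dtype=np.float64)
    direction = stats["direction"].to_numpy(dtype=object)
    significant = pvalue <= pthresh

    # post-order sweeps: significance anywhere in the subtree, and which
    # confident directions occur in the subtree (for criterion 2)
    sig_sub = significant.copy()
    has_up = direction == UP
    has_down = direction == DOWN
    sub_up = has_up.copy()
    sub_down = has_down.copy()
    for v in tree.postorder():
        for c in tree.children[v]:
            sig_sub[v] |= sig_sub[c]
            sub_up[v] |= sub_up[c]
            sub_down[v] |= sub_down[c]

    def criteria(v: int):
        """First violated criterion at significant inner node v, or None."""
        ch = tree.children[v]
        if all(significant[c] for c in ch):
            return 1
        # criterion 2 ranges over all strict descendants
        up = any(sub_up[c] for c in ch)
        down = any(sub_down[c] for c in ch)
        if up and down:
            return 2
        if any(mirv[c] <= params.mirv_thresh for c in ch):
            return 3
        return None

    def walk(start: int):
        sel: list = []
        reason: dict = {}
        skipped: dict = {}
        stack = [start]
        while stack:
            v = stack.pop()
            if not sig_sub[v]:
                continue  # branch holds no significant node: prune
            if not tree.children[v]:
                if significant[v]:
                    sel.append(v)
                    reason[v] = REASON_LEAF
                continue
            if significant[v]:
                bad = criteria(v)
                if bad is None:
                    sel.append(v)
                    reason[v] = REASON_CRITERIA
                    continue  # traversal along this branch terminates
                skipped[v] = bad
            stack.extend(reversed(tree.children[v]))
        return sel, reason, skipped

    root = tree.root
    if significant[root] and tree.children[root] and criteria(root) is None:
        logger.warning(
            "the tree root itself was selected; a root-level call carries "
            "no resolution — inspect the inputs"
        )
        result.selected = [root]
        result.reason = {root: REASON_CRITERIA}
        return result

    if n_workers > 1 and tree.children[root]:
        if sig_sub[root] and significant[root]:
            result.skipped_significant[root] = criteria(root)
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            parts = list(pool.map(walk, list(tree.children[root])))
        for sel, reason, skipped in parts:
            result.selected.extend(sel)
            result.reason.update(reason)
            result.skipped_significant.update(skipped)
    else:
        sel, reason, skipped = walk(root)
        result.selected = sel
        result.reason = reason
        result.skipped_significant = skipped

    result.selected.sort()
    assert tree.is_antichain(result.selected)
    return result


def select_over_grid(
    tree: TranscriptTree,
    stats: pd.DataFrame,
    alphas=(0.01, 0.05, 0.1),
    params: SelectionParams = SelectionParams(),
    n_workers: int = 1,
) -> dict:
    """Selection at each nominal FDR in ``alphas``.

    For each alpha the leaf BH threshold is recomputed from the tested
    (unfiltered) leaf p-values in ``stats`` and :func:`select_nodes` run.
    Returns ``{alpha: SelectionResult}``.
    """
    _validate_stats(tree, stats)
    if "is_leaf" in stats.columns:
        leaf_rows = stats["is_leaf"].to_numpy(dtype=bool)
    else:
        leaf_rows = np.zeros(tree.n_nodes, dtype=bool)
        leaf_rows[tree.leaves] = True
    tested = ~stats["filtered"].to_numpy(dtype=bool) if "filtered" in stats.columns \
        else np.ones(tree.n_nodes, dtype=bool)
    leaf_p = stats.loc[leaf_rows & tested, "pvalue"].to_numpy()

    out = {}
    for alpha in alphas:
        if leaf_p.size == 0:
            pthresh = None
        else:
            pthresh = bh_leaf_threshold(leaf_p, alpha)
        run_params = SelectionParams(
            alpha=alpha, min_p=params.min_p, mirv_thresh=params.mirv_thresh
        )
        out[alpha] = select_nodes(
            tree, stats, pthresh, params=run_params, n_workers=n_workers
        )
        logger.info(
            "alpha=%g: pthresh=%s, %d node(s) selected",
            alpha, "none" if pthresh is None else f"{pthresh:.3g}",
            len(out[alpha].selected),
        )
    return out
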