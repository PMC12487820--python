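"""Evaluation of node selections against simulated ground truth.

Node-level truth is derived from the *true* (pre-uncertainty) count matrix:
counts are aggregated to every node, the log2 ratio of condition-group
means is the node's true LFC, and a node is differentially expressed iff
its absolute LFC strictly exceeds the absolute LFC at the tree root (the
root aggregates everything, so its LFC is the baseline drift any node must
beat).  TPR/FDR are computed on the selected nodes against these labels;
the FPR sweep compares tree-based selection with plain leaf-level testing
under a null design; ``unique_branches`` isolates the nodes one method
reports that have no common, ancestral or descendant counterpart in
another method's report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import SelectionParams, select_nodes
from .tree import TranscriptTree

logger = logging.getLogger("treede")


@dataclass
class NodeTruth:
    """Per-node truth table: ``true_lfc`` and ``de`` per node ID."""

    table: pd.DataFrame
    root_lfc: float


def node_ground_truth(
    true_counts: pd.DataFrame,
    tree: TranscriptTree,
    condition,
    c0: float = 0.0,
    levels=None,
) -> NodeTruth:
    """Label every tree node DE/not-DE from true transcript counts.

    ``true_counts`` is (samples x transcripts) of noise-free counts; a node
    is DE iff |log2 ratio of group means| strictly exceeds the same
    quantity at the root.  ``c0`` is an optional pseudocount on the group
    means (default 0: with true counts the means are positive wherever a
    node is expressed; zero-mean nodes get LFC 0).
    """
    cond = np.asarray(condition)
    if levels is None:
        levels = np.unique(cond)
    if levels.size != 2:
        raise ValueError("exactly two condition levels required")
    agg = tree.aggregate(true_counts.to_numpy(dtype=np.float64),
                         list(true_counts.columns))
    mean1 = agg[cond == levels[0]].mean(axis=0) + c0
    mean2 = agg[cond == levels[1]].mean(axis=0) + c0
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean2 / mean1)
    lfc[(mean1 == 0) & (mean2 == 0)] = 0.0
    root_lfc = float(lfc[tree.root])
    de = np.abs(lfc) > abs(root_lfc)
    table = pd.DataFrame({"node": list(tree.names), "true_lfc": lfc, "de": de})
    return NodeTruth(table=table, root_lfc=root_lfc)


def tpr_fdr(
    selected,
    truth: NodeTruth,
    tree: TranscriptTree,
    universe: str = "nodes",
) -> tuple[float, float]:
    """True-positive rate and false discovery rate of a selected node set.

    Only the DE status *of the selected node itself* counts (an inner node
    is one feature; its descendants are not unpacked).  FDR = FP/|selected|
    (0 for an empty selection).  The TPR denominator depends on
    ``universe``:

    - ``"nodes"`` (default): truth-DE nodes among the leaves plus the
      selected inner nodes — the feature set the method actually ranks;
    - ``"transcripts"``: truth-DE *leaves*, with TP counted as the DE
      transcripts covered by the selected nodes (coverage mode).
    """
    selected = sorted({int(v) for v in selected})
    for v in selected:
        tree._check_node(v)
    de = truth.table["de"].to_numpy(dtype=bool)
    if not selected:
        return 0.0, 0.0
    tp = sum(bool(de[v]) for v in selected)
    fdr = (len(selected) - tp) / len(selected)
    if universe == "nodes":
        univ = set(int(v) for v in tree.leaves) | set(selected)
        denom = sum(bool(de[v]) for v in univ)
        tpr = tp / denom if denom else 0.0
    elif universe == "transcripts":
        de_leaves = {int(v) for v in tree.leaves if de[v]}
        covered: set = set()
        for v in selected:
            covered.update(tree.leaf_ids(v))
        tpr = (len(covered & de_leaves) / len(de_leaves)) if de_leaves else 0.0
    else:
        raise ValueError("universe must be 'nodes' or 'transcripts'")
    return float(tpr), float(fdr)


def covered_true_positives(selected, truth, tree: TranscriptTree) -> int:
    """Number of unique truly-DE transcripts under the selected nodes.

    ``truth`` is the simulation's transcript-level truth (any object with
    a ``de_transcripts`` attribute, e.g. ``SimTruth``) or an iterable of
    DE transcript IDs.
    """
    de = set(getattr(truth, "de_transcripts", truth))
    covered: set = set()
    for v in selected:
        covered |= set(tree.leaf_set(int(v)))
    return len(covered & de)


def fpr_sweep(
    stats: pd.DataFrame,
    tree: TranscriptTree,
    thresholds,
    params: SelectionParams = SelectionParams(),
) -> pd.DataFrame:
    """False-positive rates of tree selection vs leaf-only testing.

    For each p-value threshold ``t``, the tree method runs the full
    selection with ``pthresh = t``; its FPR is |selected| divided by the
    evaluated feature universe (tested leaves plus selected inner nodes).
    The leaf-only FPR is the fraction of tested leaves with ``p <= t``.
    Intended for null designs, where every call is a false positive.
    """
    thresholds = list(thresholds)
    if "is_leaf" in stats.columns:
        leaf_mask = stats["is_leaf"].to_numpy(dtype=bool)
    else:
        leaf_mask = np.zeros(tree.n_nodes, dtype=bool)
        leaf_mask[tree.leaves] = True
    tested = ~stats["filtered"].to_numpy(dtype=bool) if "filtered" in stats.columns \
        else np.ones(tree.n_nodes, dtype=bool)
    leaf_p = stats.loc[leaf_mask & tested, "pvalue"].to_numpy()
    if leaf_p.size == 0:
        raise ValueError("no tested leaves; FPR undefined")
    n_leaves = leaf_p.size

    rows = []
    for t in thresholds:
        sel = select_nodes(tree, stats, float(t), params=params)
        inner_sel = [v for v in sel.selected if tree.children[v]]
        universe = n_leaves + len(inner_sel)
        rows.append(
            {
                "threshold": float(t),
                "fpr_tree": len(sel.selected) / universe,
                "fpr_leaf": float((leaf_p <= t).mean()),
                "n_selected": len(sel.selected),
            }
        )
    return pd.DataFrame(rows)


def unique_branches(set_a, set_b, tree: TranscriptTree) -> set:
    """Nodes of ``set_a`` with no counterpart in ``set_b``.

    Removes nodes common to both sets, then any remaining node of ``set_a``
    that has an ancestor or descendant in ``set_b``; what is left marks the
    branches only method A reports.
    """
    a = {int(v) for v in set_a}
    b = {int(v) for v in set_b}
    for v in a | b:
        tree._check_node(v)
    out = set()
    for v in a - b:
        if any(tree.is_ancestor(w, v) or tree.is_ancestor(v, w) for w in b):
            continue
        out.add(v)
    return out


def lfc_filter_curve(
    unique_nodes,
    stats: pd.DataFrame,
    truth: NodeTruth,
    lfc_grid,
) -> pd.DataFrame:
    """Empirical FDR and node count after filtering unique nodes by |LFC|.

    At each cutoff, nodes with observed ``|lfc| >= cutoff`` (from the
    ``lfc`` column of ``stats``) are kept; the FDR is recomputed on the
    kept set against the node truth (NaN when nothing is left).
    """
    nodes = sorted({int(v) for v in unique_nodes})
    lfc = stats["lfc"].to_numpy(dtype=np.float64)
    de = truth.table["de"].to_numpy(dtype=bool)
    rows = []
    for cut in lfc_grid:
        kept = [v for v in nodes if abs(lfc[v]) >= cut]
        if kept:
            fp = sum(not de[v] for v in kept)
            fdr = fp / len(kept)
        else:
            fdr = float("nan")
        rows.append({"lfc_cutoff": float(cut), "fdr": fdr, "n_nodes": len(kept)})
    return pd.DataFrame(rows)
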