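"""Rooted transcript trees and inferential-replicate count containers.

A transcript tree has transcripts at its leaves and transcript *groups* at
its inner nodes; the group associated with a node is the set of transcripts
descending from it.  Trees of this kind are produced by uncertainty-aware
grouping tools upstream of differential testing, with estimation uncertainty
generally decreasing toward the root.  This module owns the tree container,
newick I/O, forest unification, count aggregation and the topology queries
(leaf sets, heights, ancestor tests, antichain checks) that every other part
of the package relies on.

Node identifiers are integers ``0..N-1`` assigned in post-order during
construction, so the root is always ``N-1`` and identical inputs yield
identical numbering on any platform.  Leaf names are the transcript IDs;
inner nodes keep any name present in the newick and otherwise get a stable
synthetic name ``"N<k>"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np


class TreeError(ValueError):
    """Raised for malformed trees, unknown nodes or inconsistent inputs."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TranscriptTree:
    """Rooted tree over transcripts with post-order integer node IDs.

    Attributes
    ----------
    parent : ndarray of int
        ``parent[i]`` is the parent of node ``i``; ``-1`` for the root.
    children : list of list of int
        Ordered children per node; empty for leaves.
    names : list of str
        Node names; transcript IDs for leaves, synthetic or newick-supplied
        names for inner nodes.
    """

    parent: np.ndarray
    children: list
    names: list
    _tin: np.ndarray = field(default=None, repr=False, compare=False)
    _tout: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        n = self.parent.size
        if n == 0:
            raise TreeError("empty tree")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        leaves = [i for i in range(n) if not self.children[i]]
        labels = [self.names[i] for i in leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf transcript IDs: {dupes[:5]}")
        self._leaves = np.asarray(leaves, dtype=np.int64)
        self._index_euler()

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def leaves(self) -> np.ndarray:
        """Node IDs of all leaves."""
        return self._leaves

    @property
    def inner_nodes(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self._leaves] = False
        return np.flatnonzero(mask)

    @property
    def leaf_labels(self) -> dict:
        return {int(i): self.names[i] for i in self._leaves}

    def is_leaf(self, node: int) -> bool:
        self._check_node(node)
        return len(self.children[node]) == 0

    def _check_node(self, node: int) -> None:
        if not (0 <= int(node) < self.n_nodes):
            raise TreeError(f"unknown node {node!r}")

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> np.ndarray:
        """Node IDs in post-order (children before parents).

        With post-order construction this is simply ``0..N-1``, but the
        method recomputes it from the topology so it stays correct for
        trees built by other means.
        """
        order = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    def _index_euler(self) -> None:
        """Entry/exit times of a DFS, for O(1) ancestor queries."""
        n = self.n_nodes
        tin = np.empty(n, dtype=np.int64)
        tout = np.empty(n, dtype=np.int64)
        t = 0
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                tout[node] = t
                t += 1
            else:
                tin[node] = t
                t += 1
                stack.append((node, True))
                for c in reversed(self.children[node]):
                    stack.append((c, False))
        self._tin, self._tout = tin, tout

    # -- queries ------------------------------------------------------------

    def leaf_set(self, node: int) -> frozenset:
        """Transcript IDs descending from ``node`` (the node's group)."""
        self._check_node(node)
        return frozenset(self.names[i] for i in self.leaf_ids(node))

    def leaf_ids(self, node: int) -> list:
        """Leaf node IDs in the subtree rooted at ``node``."""
        self._check_node(node)
        out = []
        stack = [int(node)]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def node_height(self, node: int) -> int:
        """Maximum distance (in edges) from ``node`` down to its leaves."""
        self._check_node(node)
        return int(self.heights()[int(node)])

    def heights(self) -> np.ndarray:
        h = np.zeros(self.n_nodes, dtype=np.int64)
        for v in self.postorder():
            if self.children[v]:
                h[v] = 1 + max(h[c] for c in self.children[v])
        return h

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``b`` lies in the proper subtree of ``a``."""
        self._check_node(a)
        self._check_node(b)
        a, b = int(a), int(b)
        if a == b:
            return False
        return self._tin[a] < self._tin[b] and self._tout[b] <= self._tout[a]

    def is_antichain(self, nodes: Iterable[int]) -> bool:
        """True iff no pair in ``nodes`` is in an ancestor/descendant
        relation, i.e. the nodes' transcript groups are pairwise disjoint."""
        ids = sorted({int(v) for v in nodes}, key=lambda v: self._tin[v])
        for v in ids:
            self._check_node(v)
        last_out = -1
        for v in ids:
            if self._tin[v] < last_out:
                return False
            last_out = self._tout[v]
        return True

    # -- aggregation ---------------------------------------------------------

    def aggregate(self, leaf_values: np.ndarray, feature_ids: Sequence[str]) -> np.ndarray:
        """Sum leaf values up the tree.

        Parameters
        ----------
        leaf_values : ndarray
            Values with the *second* axis indexing features (any shape
            ``(S, F)`` or ``(S, F, R)``); columns are matched to leaves by
            ``feature_ids`` and must cover every leaf.

        Returns
        -------
        ndarray with the feature axis expanded to all ``N`` nodes, in node-ID
        order; leaf columns pass through unchanged.
        """
        leaf_values = np.asarray(leaf_values)
        col = {t: j for j, t in enumerate(feature_ids)}
        missing = [self.names[i] for i in self._leaves if self.names[i] not in col]
        if missing:
            raise TreeError(f"leaf transcripts missing from matrix: {missing[:5]}")
        shape = list(leaf_values.shape)
        shape[1] = self.n_nodes
        out = np.zeros(shape, dtype=np.float64)
        for i in self._leaves:
            out[:, i, ...] = leaf_values[:, col[self.names[i]], ...]
        for v in self.postorder():
            ch = self.children[v]
            if ch:
                out[:, v, ...] = out[:, ch, ...].sum(axis=1)
        return out

    # -- newick -------------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(name: str) -> str:
            if any(c in name for c in "(),:;'[] \t"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def rec(v: int) -> str:
            if not self.children[v]:
                return fmt(self.names[v])
            inner = ",".join(rec(c) for c in self.children[v])
            return f"({inner}){fmt(self.names[v])}"

        return rec(self.root) + ";"


@dataclass
class ReplicateTensor:
    """Per-sample estimated counts with inferential replicates.

    ``counts`` has shape ``(n_samples, n_features, n_replicates)`` holding
    one count matrix per inferential replicate (bootstrap or posterior
    samples of the quantification); ``point`` is the point-estimate matrix
    ``(n_samples, n_features)``.
    """

    counts: np.ndarray
    point: np.ndarray
    feature_ids: list
    sample_ids: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.point = np.asarray(self.point, dtype=np.float64)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (samples, features, replicates)")
        s, f, r = self.counts.shape
        if self.point.shape != (s, f):
            raise ValueError("point shape must match counts (samples, features)")
        if len(self.feature_ids) != f or len(self.sample_ids) != s:
            raise ValueError("feature/sample ID lengths do not match counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[2]

    @classmethod
    def from_replicates(cls, counts, feature_ids, sample_ids, point=None):
        """Build a tensor, defaulting the point estimate to the replicate mean."""
        counts = np.asarray(counts, dtype=np.float64)
        if point is None:
            point = counts.mean(axis=2)
        return cls(counts, np.asarray(point, dtype=np.float64),
                   list(feature_ids), list(sample_ids))

    def aggregate(self, tree: TranscriptTree) -> "ReplicateTensor":
        """Aggregate leaf-level counts to every node of ``tree``."""
        counts = tree.aggregate(self.counts, self.feature_ids)
        point = tree.aggregate(self.point, self.feature_ids)
        return ReplicateTensor(counts, point, list(tree.names), list(self.sample_ids))

    def scaled(self, size_factors: np.ndarray) -> "ReplicateTensor":
        sf = np.asarray(size_factors, dtype=np.float64)
        if sf.shape != (self.n_samples,):
            raise ValueError("one size factor per sample required")
        if np.any(sf <= 0):
            raise ValueError("size factors must be positive")
        return ReplicateTensor(
            self.counts / sf[:, None, None],
            self.point / sf[:, None],
            list(self.feature_ids),
            list(self.sample_ids),
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> TranscriptTree:
    order = list(dtree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    children: list = [[] for _ in range(n)]
    names = [""] * n
    k = 0
    for i, nd in enumerate(order):
        for ch in nd.child_nodes():
            j = index[id(ch)]
            parent[j] = i
            children[i].append(j)
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is None:
                raise TreeError("leaf without a name in newick input")
            names[i] = str(label)
        else:
            if nd.label:
                names[i] = str(nd.label)
            else:
                names[i] = f"N{k}"
            k += 1
    return TranscriptTree(parent, children, names)


def parse_newick(text: str) -> TranscriptTree:
    """Parse a newick string into a :class:`TranscriptTree`.

    Branch lengths, if present, are read and discarded: no downstream
    computation uses them.  Inner-node names in the input are preserved;
    unnamed inner nodes receive deterministic post-order names.
    """
    if not text or not text.strip():
        raise TreeError("empty newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None or (dtree.seed_node.is_leaf()
                                   and dtree.seed_node.taxon is None):
        raise TreeError("newick string contains no tree")
    return _from_dendropy(dtree)


def write_newick(tree: TranscriptTree) -> str:
    return tree.to_newick()


def from_nested(spec) -> TranscriptTree:
    """Build a tree from nested tuples/lists of leaf names.

    ``from_nested((("A", "B"), "C"))`` gives the same topology as parsing
    ``"((A,B),C);"``.  A bare string builds a single leaf under itself.
    """
    parent: list = []
    children: list = []
    names: list = []

    def rec(node) -> int:
        if isinstance(node, str):
            parent.append(-1)
            children.append([])
            names.append(node)
            return len(parent) - 1
        ch = [rec(c) for c in node]
        parent.append(-1)
        children.append(ch)
        names.append("")
        me = len(parent) - 1
        for c in ch:
            parent[c] = me
        return me

    rec(spec)
    k = 0
    for i, nm in enumerate(names):
        if children[i] and not nm:
            names[i] = f"N{k}"
            k += 1
    return TranscriptTree(np.asarray(parent), children, names)


def unify_forest(trees: Sequence[TranscriptTree], all_transcripts: Sequence[str]) -> TranscriptTree:
    """Join a forest into one tree over a full transcript set.

    A new synthetic root is created whose children are the roots of the
    input trees plus one direct leaf child per transcript in
    ``all_transcripts`` not covered by any tree.  Input trees must have
    pairwise-disjoint leaf sets, all contained in ``all_transcripts``.
    """
    covered: set = set()
    for t in trees:
        labels = set(t.leaf_labels.values())
        if labels & covered:
            raise TreeError(f"overlapping leaf sets between trees: "
                            f"{sorted(labels & covered)[:5]}")
        covered |= labels
    universe = list(all_transcripts)
    if len(set(universe)) != len(universe):
        raise TreeError("duplicate transcript IDs in all_transcripts")
    extra = covered - set(universe)
    if extra:
        raise TreeError(f"tree leaves not in all_transcripts: {sorted(extra)[:5]}")
    orphans = [t for t in universe if t not in covered]

    parent: list = []
    children: list = []
    names: list = []

    def copy_tree(src: TranscriptTree) -> int:
        offset = len(parent)
        remap = {}
        for v in src.postorder():
            remap[int(v)] = len(parent)
            parent.append(-1)
            children.append([remap[int(c)] for c in src.children[v]])
            names.append(src.names[v])
            for c in src.children[v]:
                parent[remap[int(c)]] = remap[int(v)]
        del offset
        return remap[src.root]

    top: list = []
    for t in trees:
        top.append(copy_tree(t))
    for name in orphans:
        parent.append(-1)
        children.append([])
        names.append(name)
        top.append(len(parent) - 1)
    root = len(parent)
    parent.append(-1)
    children.append(top)
    names.append("")
    for c in top:
        parent[c] = root

    # renumber to post-order and make inner names unique
    tree = TranscriptTree(np.asarray(parent), children, names)
    tree = _renumber_postorder(tree)
    seen: set = set()
    k = 0
    for i in range(tree.n_nodes):
        if tree.children[i]:
            nm = tree.names[i]
            if not nm or nm in seen:
                while f"N{k}" in seen:
                    k += 1
                tree.names[i] = f"N{k}"
            seen.add(tree.names[i])
    return tree


def _renumber_postorder(tree: TranscriptTree) -> TranscriptTree:
    order = tree.postorder()
    remap = {int(v): i for i, v in enumerate(order)}
    n = tree.n_nodes
    parent = np.full(n, -1, dtype=np.int64)
    children: list = [[] for _ in range(n)]
    names = [""] * n
    for v in range(n):
        i = remap[v]
        names[i] = tree.names[v]
        children[i] = [remap[int(c)] for c in tree.children[v]]
        if tree.parent[v] >= 0:
            parent[i] = remap[int(tree.parent[v])]
    return TranscriptTree(parent, children, names)
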