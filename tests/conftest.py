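import numpy as np
import pandas as pd
import pytest

import treede as td


def random_tree(rng: np.random.Generator, n_leaves: int) -> td.TranscriptTree:
    """Random tree (with polytomies) over n_leaves named leaves."""
    roots = [f"t{i}" for i in range(n_leaves)]
    while len(roots) > 1:
        k = min(len(roots), int(rng.integers(2, 5)))
        picks = sorted(rng.choice(len(roots), size=k, replace=False), reverse=True)
        merged = tuple(roots.pop(i) for i in picks)
        roots.insert(int(rng.integers(0, len(roots) + 1)), merged)
    return td.from_nested(roots[0])


def random_stats(rng: np.random.Generator, tree: td.TranscriptTree,
                 sig_frac: float = 0.4) -> pd.DataFrame:
    """Random per-node stats with a decent share of small p-values."""
    n = tree.n_nodes
    pvalue = rng.uniform(0, 1, size=n)
    boost = rng.random(n) < sig_frac
    pvalue[boost] *= 0.1
    return pd.DataFrame({
        "pvalue": pvalue,
        "mean_infrv": rng.uniform(0.0, 1.0, size=n),
        "direction": rng.choice([td.uncertainty.UP, td.uncertainty.DOWN,
                                 td.uncertainty.UNSURE], size=n),
    })


def oracle_select(tree: td.TranscriptTree, stats: pd.DataFrame, pthresh,
                  params: td.SelectionParams) -> set:
    """Literal, closed-form reference for the node selector.

    A node is *eligible* if it is significant and is either a leaf or an
    inner node satisfying all three selection rules, each evaluated by
    brute force on leaf sets; the selected set is the eligible nodes with
    no eligible proper ancestor.
    """
    if pthresh is None:
        return set()
    p = stats["pvalue"].to_numpy()
    mirv = stats["mean_infrv"].to_numpy()
    direction = stats["direction"].to_numpy(dtype=object)
    sig = p <= pthresh

    def strict_descendants(v):
        out = []
        stack = list(tree.children[v])
        while stack:
            w = stack.pop()
            out.append(w)
            stack.extend(tree.children[w])
        return out

    def eligible(v):
        if not sig[v]:
            return False
        ch = tree.children[v]
        if not ch:
            return True
        if all(sig[c] for c in ch):
            return False
        dirs = {direction[d] for d in strict_descendants(v)
                if direction[d] in (td.uncertainty.UP, td.uncertainty.DOWN)}
        if len(dirs) > 1:
            return False
        if any(mirv[c] <= params.mirv_thresh for c in ch):
            return False
        return True

    elig = {v for v in range(tree.n_nodes) if eligible(v)}
    out = set()
    for v in elig:
        a = int(tree.parent[v])
        blocked = False
        while a >= 0:
            if a in elig:
                blocked = True
                break
            a = int(tree.parent[a])
        if not blocked:
            out.add(v)
    return out


@pytest.fixture
def small_tree():
    return td.parse_newick("((A,B),C);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
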