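"""Inferential uncertainty of node abundances.

RNA-seq quantification produces, per sample, not just a point estimate of
each feature's count but a set of inferential replicates (bootstrap or
posterior Gibbs samples).  The *inferential relative variance* (infRV)
summarises how much those replicates disagree, relative to the feature's
abundance::

    infRV = max(var - mean, 0) / (mean + pc) + d

where the variance and mean are taken over the inferential replicates,
``pc`` is a pseudocount (default 5) and ``d`` a small global shift
(default 0.01).  A Poisson-like feature (variance <= mean) sits at the
floor ``d``; features whose reads are shared with sequence-similar
transcripts show excess replicate variance and a large infRV.

``mean_infrv`` averages the per-sample infRV over samples, per tree node
(aggregating replicate counts to the node first).  ``sign_direction``
calls the direction of change between two conditions per node, requiring
the same sign of the per-replicate log fold change in at least a fraction
``min_p`` of the replicates before committing to "up" or "down".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import ReplicateTensor, TranscriptTree

UP, DOWN, UNSURE = "up", "down", "unsure"


@dataclass(frozen=True)
class InfRVParams:
    """Pseudocount and floor of the inferential relative variance."""

    pc: float = 5.0
    d: float = 0.01

    def __post_init__(self):
        if self.pc <= 0:
            raise ValueError("pseudocount pc must be > 0")
        if self.d < 0:
            raise ValueError("global shift d must be >= 0")


def infrv(mean, variance, params: InfRVParams = InfRVParams()):
    """Inferential relative variance of a feature in one sample.

    Accepts scalars or arrays (broadcast together).
    """
    mean = np.asarray(mean, dtype=np.float64)
    variance = np.asarray(variance, dtype=np.float64)
    if np.any(mean < 0) or np.any(variance < 0):
        raise ValueError("mean and variance must be nonnegative")
    out = np.maximum(variance - mean, 0.0) / (mean + params.pc) + params.d
    if out.ndim == 0:
        return float(out)
    return out


def mean_infrv(
    tensor: ReplicateTensor,
    tree: TranscriptTree | None = None,
    params: InfRVParams = InfRVParams(),
) -> np.ndarray:
    """Per-feature infRV averaged over samples.

    If ``tree`` is given, leaf-level replicate counts are aggregated to every
    node first and one value per node is returned (node-ID order); otherwise
    one value per tensor feature.  Requires at least two inferential
    replicates for the variance to be defined.
    """
    if tensor.n_replicates < 2:
        raise ValueError(
            "mean_infrv requires >= 2 inferential replicates per sample"
        )
    counts = tensor.aggregate(tree).counts if tree is not None else tensor.counts
    mu = counts.mean(axis=2)
    var = counts.var(axis=2, ddof=1)
    per_sample = infrv(mu, var, params)  # (samples, features)
    return np.asarray(per_sample).mean(axis=0)


def _condition_masks(condition, sample_ids=None, levels=None):
    """Split samples into two groups; returns (levels, mask1, mask2)."""
    cond = np.asarray(condition)
    if levels is None:
        levels = np.unique(cond)
    else:
        levels = np.asarray(levels)
    if levels.size != 2:
        raise ValueError(f"exactly two condition levels required, got {list(levels)}")
    m1 = cond == levels[0]
    m2 = cond == levels[1]
    if not (m1 | m2).all():
        raise ValueError("condition contains labels outside the two levels")
    if m1.sum() == 0 or m2.sum() == 0:
        raise ValueError("each condition level needs at least one sample")
    return levels, m1, m2


def replicate_lfc(
    counts: np.ndarray, condition, c0: float = 1.0, levels=None
) -> np.ndarray:
    """Per-replicate log2 fold change of condition means.

    ``counts`` is ``(samples, features, replicates)``; the result is
    ``(features, replicates)`` with LFC = log2((mean over level-2 samples
    + c0) / (mean over level-1 samples + c0)).  The pseudocount ``c0``
    guards against zero counts.
    """
    counts = np.asarray(counts, dtype=np.float64)
    _, m1, m2 = _condition_masks(condition, levels=levels)
    if m1.size != counts.shape[0]:
        raise ValueError("condition length does not match number of samples")
    mean1 = counts[m1].mean(axis=0)
    mean2 = counts[m2].mean(axis=0)
    return np.log2((mean2 + c0) / (mean1 + c0))


def sign_directions(
    counts: np.ndarray,
    condition,
    min_p: float = 0.70,
    c0: float = 1.0,
    levels=None,
    strict: bool = False,
) -> np.ndarray:
    """Directional call per feature from per-replicate fold changes.

    A feature is "up" ("down") if the per-replicate LFC is positive
    (negative) in at least a fraction ``min_p`` of the inferential
    replicates; otherwise "unsure".  Replicates with LFC exactly zero count
    toward neither direction.  ``strict=True`` demands strictly more than
    ``min_p``.
    """
    if not (0.5 < min_p <= 1.0):
        raise ValueError("min_p must lie in (0.5, 1]")
    lfc = replicate_lfc(counts, condition, c0=c0, levels=levels)
    r = lfc.shape[1]
    frac_up = (lfc > 0).sum(axis=1) / r
    frac_down = (lfc < 0).sum(axis=1) / r
    if strict:
        up = frac_up > min_p
        down = frac_down > min_p
    else:
        up = frac_up >= min_p
        down = frac_down >= min_p
    out = np.full(lfc.shape[0], UNSURE, dtype=object)
    out[up] = UP
    out[down] = DOWN
    return out


def sign_direction(
    tensor: ReplicateTensor, node, condition, min_p: float = 0.70, **kw
) -> str:
    """Directional call for a single tensor feature (by index or ID)."""
    if isinstance(node, str):
        try:
            node = tensor.feature_ids.index(node)
        except ValueError:
            raise KeyError(f"unknown feature {node!r}") from None
    counts = tensor.counts[:, [int(node)], :]
    return str(sign_directions(counts, condition, min_p=min_p, **kw)[0])
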