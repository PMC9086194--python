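"""Rank aggregation of base-selector outputs, candidate expansion and block building.

The ensemble's first phase turns heterogeneous selector outputs into a single
"best position achieved" rank per feature, collects the union of selected
features, expands it with features highly correlated to a selected one, and
partitions the resulting candidate set into correlation blocks that the group
lasso will penalize jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import complete, fcluster
from scipy.spatial.distance import squareform

from .base_selectors import SelectorOutput

__all__ = [
    "RankAggregation",
    "BlockPartition",
    "selector_rank_vector",
    "aggregate_ranks",
    "expand_candidates",
    "form_blocks",
]


@dataclass
class RankAggregation:
    """Aggregated best-position ranks and the candidate feature set.

    ``agg_rank[j]`` is the minimum (best) rank feature j achieved across the
    base selectors.  ``candidates`` are 0-based feature indices; ``expanded``
    flags the members that entered via correlation expansion rather than by
    being picked by a base selector.
    """

    G: int
    agg_rank: np.ndarray  # (G,) int, 1..G
    base_selected: np.ndarray  # sorted indices picked by >=1 selector
    candidates: np.ndarray | None = None  # sorted indices, after expansion
    expanded: np.ndarray | None = None  # bool mask aligned with candidates

    def candidate_ranks(self) -> np.ndarray:
        """Rank each candidate carries into block weighting.

        Correlation-expanded members that no selector picked carry the worst
        rank G; base-selected members carry their aggregated rank.
        """
        if self.candidates is None:
            raise ValueError("candidates not set; run expand_candidates first")
        r = np.full(self.candidates.size, self.G, dtype=np.int64)
        base = np.isin(self.candidates, self.base_selected)
        r[base] = self.agg_rank[self.candidates[base]]
        return r


@dataclass
class BlockPartition:
    """Correlation blocks over the candidate set with group penalty weights.

    ``assignment[i]`` gives the 0-based block of candidate i;
    ``weights[b] = (min candidate rank in block b) * sqrt(block size)`` — the
    rank factor penalizes top-ranked blocks least, and the sqrt-size factor is
    the standard group-lasso multiplier that keeps blocks of different sizes
    comparable.
    """

    candidates: np.ndarray  # (p,) feature indices
    assignment: np.ndarray  # (p,) ints 0..B-1
    rho: float
    weights: np.ndarray  # (B,)

    @property
    def p(self) -> int:
        return int(self.candidates.size)

    @property
    def n_blocks(self) -> int:
        return int(self.assignment.max()) + 1 if self.p else 0

    @property
    def block_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_blocks)

    def members(self, b: int) -> np.ndarray:
        """Feature indices (into the full matrix) of block ``b``."""
        return self.candidates[self.assignment == b]


def selector_rank_vector(out: SelectorOutput) -> np.ndarray:
    """Convert one selector output into a full rank vector of length G.

    Ranking outputs pass through.  Ordered subsets map to ranks 1..k in order.
    Unordered subsets tie all selected features at rank 1.  Unselected features
    tie at the worst rank G.
    """
    G = out.G
    if out.output_type == "ranking":
        return out.ranks.copy()
    ranks = np.full(G, G, dtype=np.int64)
    sel = out.selected
    if sel is None or sel.size == 0:
        return ranks
    if out.output_type == "ordered_subset":
        ranks[sel] = np.arange(1, sel.size + 1)
    else:
        ranks[sel] = 1
    return ranks


def aggregate_ranks(outputs: list[SelectorOutput]) -> RankAggregation:
    """Aggregate selector outputs into best-position ranks + base candidate set.

    A feature ranked 1st by one selector and 10th by another aggregates to 1.
    """
    if not outputs:
        raise ValueError("need at least one selector output")
    G = outputs[0].G
    if any(o.G != G for o in outputs):
        raise ValueError("selector outputs disagree on the feature count G")
    rank_matrix = np.stack([selector_rank_vector(o) for o in outputs])
    agg = rank_matrix.min(axis=0)
    base = sorted(set().union(*(o.selected_set for o in outputs)))
    return RankAggregation(
        G=G, agg_rank=agg, base_selected=np.asarray(base, dtype=np.int64)
    )


def _abs_corr(X: np.ndarray) -> np.ndarray:
    """|Pearson correlation| with zero-variance columns treated as uncorrelated."""
    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    Z = Xc / safe
    C = np.abs(Z.T @ Z / X.shape[0])
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


def expand_candidates(agg: RankAggregation, X: np.ndarray, rho: float) -> RankAggregation:
    """Grow the base-selected set by one correlation pass.

    A feature joins the candidate set if its |correlation| with some
    base-selected feature exceeds ``rho``.  The pass is not transitive: features
    correlated only with an expanded member stay out.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != agg.G:
        raise ValueError("X column count disagrees with G")
    base = agg.base_selected
    if base.size == 0:
        raise ValueError("base candidate set is empty")
    sd = X.std(axis=0)
    Xc = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    C = np.abs(Xc.T @ Xc[:, base] / X.shape[0])  # (G, |base|)
    C[sd == 0, :] = 0.0
    C[:, sd[base] == 0] = 0.0
    hit = (C > rho).any(axis=1)
    hit[base] = True
    candidates = np.flatnonzero(hit)
    agg.candidates = candidates
    agg.expanded = ~np.isin(candidates, base)
    return agg


def form_blocks(
    agg: RankAggregation, X: np.ndarray, rho: float
) -> BlockPartition:
    """Partition candidates into blocks with all pairwise |corr| > rho.

    Complete-linkage agglomerative clustering on distance 1 - |corr| cut at
    height 1 - rho guarantees the all-pairs property by construction.  Penalty
    weight per block = (best aggregated rank among members) x sqrt(block size),
    the usual group-lasso size multiplier scaled by how highly the base
    selectors ranked the block's best member.
    """
    if agg.candidates is None:
        raise ValueError("run expand_candidates before form_blocks")
    cand = agg.candidates
    p = cand.size
    if p == 0:
        raise ValueError("candidate set is empty")
    if p == 1:
        assignment = np.zeros(1, dtype=np.int64)
    else:
        C = _abs_corr(np.asarray(X, dtype=float)[:, cand])
        D = np.clip(1.0 - C, 0.0, None)
        np.fill_diagonal(D, 0.0)
        Z = complete(squareform(D, checks=False))
        # cut strictly below 1 - rho so pairs at exactly rho stay separate
        labels = fcluster(Z, t=(1.0 - rho) * (1 - 1e-12), criterion="distance")
        # relabel 0..B-1 in order of first appearance for determinism
        _, assignment = np.unique(labels, return_inverse=True)
    ranks = agg.candidate_ranks()
    B = int(assignment.max()) + 1
    weights = np.empty(B)
    for b in range(B):
        m = assignment == b
        weights[b] = ranks[m].min() * np.sqrt(m.sum())
    return BlockPartition(candidates=cand, assignment=assignment, rho=rho, weights=weights)
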