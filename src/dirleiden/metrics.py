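"""Partition-comparison metrics for ground-truth validation.

Everything needed to score a detected partition against a planted one:
normalized mutual information, the classic pair-counting Rand index and its
edge-restricted ("graph-structural") variant, label-invariant vertex-level
agreement, community counts and inter-community edge-weight block sums.
All metrics are symmetric in their two partitions and invariant under
community relabeling.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .graph import CSRGraph, Membership

logger = logging.getLogger("dirleiden")


@dataclass(frozen=True)
class MetricReport:
    """Bundle of every partition-similarity number the evaluator emits."""

    nmi: float
    rand: float
    structural_rand: float
    agreement_pct: float
    n_communities_a: int
    n_communities_b: int
    inter_weight_delta: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_lengths(a: Membership, b: Membership) -> int:
    if len(a) != len(b):
        raise ValueError(f"partition lengths differ: {len(a)} vs {len(b)}")
    return len(a)


def contingency(a: Membership, b: Membership) -> np.ndarray:
    """Dense contingency table n_ij = |A_i intersect B_j|."""
    _check_lengths(a, b)
    ka, kb = a.n_communities, b.n_communities
    idx = a.assign * np.int64(kb) + b.assign
    return np.bincount(idx, minlength=ka * kb).reshape(ka, kb)


# ---------------------------------------------------------------------------
# information-theoretic
# ---------------------------------------------------------------------------

def nmi(a: Membership, b: Membership) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    NMI = 2 I(A;B) / (H(A) + H(B)).  Two zero-entropy (single-community)
    partitions are identical in structure and score 1; exactly one
    zero-entropy partition scores 0.
    """
    n = _check_lengths(a, b)
    if n == 0:
        return 1.0
    tab = contingency(a, b).astype(np.float64)
    pa = tab.sum(axis=1) / n
    pb = tab.sum(axis=0) / n
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha == 0.0 and hb == 0.0:
        return 1.0
    if ha == 0.0 or hb == 0.0:
        return 0.0
    # identical structure up to relabeling: exactly one block per row/column
    nz = tab > 0
    if (nz.sum(axis=0) == 1).all() and (nz.sum(axis=1) == 1).all():
        return 1.0
    pij = tab / n
    outer = np.outer(pa, pb)
    mask = pij > 0
    mi = np.sum(pij[mask] * np.log(pij[mask] / outer[mask]))
    return float(max(0.0, min(1.0, 2.0 * mi / (ha + hb))))


# ---------------------------------------------------------------------------
# pair counting
# ---------------------------------------------------------------------------

def rand_index(a: Membership, b: Membership) -> float:
    """Fraction of unordered node pairs on which the partitions agree."""
    n = _check_lengths(a, b)
    if n < 2:
        return 1.0
    tab = contingency(a, b).astype(np.float64)
    comb = lambda x: x * (x - 1.0) / 2.0
    total = comb(float(n))
    same_same = comb(tab).sum()
    same_a = comb(tab.sum(axis=1)).sum()
    same_b = comb(tab.sum(axis=0)).sum()
    split_split = total - same_a - same_b + same_same
    return float((same_same + split_split) / total)


def structural_rand(g: CSRGraph, a: Membership, b: Membership) -> float:
    """Rand agreement restricted to node pairs joined by an edge of ``g``.

    The pair universe is the adjacent pairs (self-loops excluded); 1 means
    the two partitions make identical same/split decisions on every edge.
    """
    n = _check_lengths(a, b)
    if n != g.n:
        raise ValueError("graph size does not match partitions")
    src, dst, _ = g.edge_triples()
    keep = src < dst if not g.directed else src != dst
    src, dst = src[keep], dst[keep]
    if src.shape[0] == 0:
        raise ValueError("structural Rand index needs at least one non-loop edge")
    same_a = a.assign[src] == a.assign[dst]
    same_b = b.assign[src] == b.assign[dst]
    return float(np.mean(same_a == same_b))


# ---------------------------------------------------------------------------
# vertex-level agreement
# ---------------------------------------------------------------------------

def membership_agreement(a: Membership, b: Membership) -> float:
    """Maximum percentage of nodes with equal labels over label bijections.

    Solved exactly at any size with the Hungarian algorithm on the
    contingency table (pad to square, maximize the matched mass).
    """
    n = _check_lengths(a, b)
    if n == 0:
        return 100.0
    tab = contingency(a, b)
    rows, cols = linear_sum_assignment(tab, maximize=True)
    matched = tab[rows, cols].sum()
    return float(100.0 * matched / n)


def raw_label_agreement(a: Membership, b: Membership) -> float:
    """Percentage of nodes whose raw labels coincide (no matching)."""
    n = _check_lengths(a, b)
    if n == 0:
        return 100.0
    return float(100.0 * np.mean(a.assign == b.assign))


# ---------------------------------------------------------------------------
# community structure summaries
# ---------------------------------------------------------------------------

def community_count(p: Membership) -> int:
    """Number of non-empty communities."""
    return int(np.unique(p.assign).shape[0])


def inter_community_weights(g: CSRGraph, p: Membership) -> np.ndarray:
    """K x K block-sum matrix of edge weight between community pairs.

    Off-diagonal entry (C, D) is the summed weight of edges from C to D
    (symmetric for undirected graphs); the diagonal holds intra-community
    weight with every edge counted once.  The diagonal plus, for directed
    graphs the full off-diagonal part and for undirected graphs one
    triangle of it, sums to ``m``.
    """
    if len(p) != g.n:
        raise ValueError("membership length does not match the graph")
    k = p.n_communities
    proj = sp.csr_matrix(
        (np.ones(g.n), (np.arange(g.n), p.assign)), shape=(g.n, k))
    block = np.asarray((proj.T @ g.to_scipy() @ proj).todense())
    if not g.directed:
        loops = np.bincount(p.assign, weights=g.self_loop, minlength=k)
        np.fill_diagonal(block, (np.diag(block) + loops) / 2.0)
    return block


def inter_weight_delta(g: CSRGraph, a: Membership, b: Membership) -> float:
    """Total absolute difference between the two block-sum matrices.

    Blocks are aligned with the optimal label matching of
    :func:`membership_agreement`; unmatched communities compare against
    zero.  0 means the inter-community weight structure is identical.
    """
    tab = contingency(a, b)
    rows, cols = linear_sum_assignment(tab, maximize=True)
    ka, kb = a.n_communities, b.n_communities
    k = max(ka, kb)
    wa = np.zeros((k, k))
    wb = np.zeros((k, k))
    wa[:ka, :ka] = inter_community_weights(g, a)
    # remap b's blocks into a's label frame via the optimal assignment;
    # unmatched b communities take the free label slots
    mapped = np.full(kb, -1)
    mapped[cols] = rows
    free = iter(sorted(set(range(k)) - set(rows.tolist())))
    for i in np.flatnonzero(mapped < 0):
        mapped[i] = next(free)
    wb_raw = inter_community_weights(g, b)
    wb[np.ix_(mapped, mapped)] = wb_raw
    return float(np.abs(wa - wb).sum())


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

def evaluate(a: Membership, b: Membership, g: CSRGraph | None = None
             ) -> MetricReport:
    """Full similarity report of partition ``a`` against reference ``b``."""
    report = MetricReport(
        nmi=nmi(a, b),
        rand=rand_index(a, b),
        structural_rand=structural_rand(g, a, b) if g is not None else float("nan"),
        agreement_pct=membership_agreement(a, b),
        n_communities_a=community_count(a),
        n_communities_b=community_count(b),
        inter_weight_delta=(inter_weight_delta(g, a, b)
                            if g is not None else float("nan")),
    )
    logger.debug("raw (unmatched) label agreement: %.2f%%",
                 raw_label_agreement(a, b))
    return report
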