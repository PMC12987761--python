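"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation paths they check:
modularity is recomputed from dense matrices, transposition from a
sort-based reference, optima from exhaustive set-partition enumeration.
"""

import numpy as np
import pytest

from dirleiden import CSRGraph, Membership


# ---------------------------------------------------------------------------
# dense-matrix modularity oracles
# ---------------------------------------------------------------------------

def dense_adjacency(g: CSRGraph) -> np.ndarray:
    """Dense adjacency; undirected self-loops doubled (A_ii = 2w)."""
    a = np.zeros((g.n, g.n))
    src, dst, w = g.edge_triples()
    for u, v, ww in zip(src, dst, w):
        a[u, v] += ww
    if not g.directed:
        for u in range(g.n):
            a[u, u] *= 2.0
    return a


def dense_modularity_undirected(g: CSRGraph, p: Membership, gamma=1.0) -> float:
    a = dense_adjacency(g)
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    delta = (p.assign[:, None] == p.assign[None, :])
    return float(((a - gamma * np.outer(k, k) / two_m) * delta).sum() / two_m)


def dense_modularity_directed(g: CSRGraph, p: Membership, gamma=1.0) -> float:
    a = dense_adjacency(g)
    m = a.sum()
    if m == 0:
        return 0.0
    k_out = a.sum(axis=1)
    k_in = a.sum(axis=0)
    delta = (p.assign[:, None] == p.assign[None, :])
    return float(((a - gamma * np.outer(k_out, k_in) / m) * delta).sum() / m)


# ---------------------------------------------------------------------------
# sort-based transpose oracle
# ---------------------------------------------------------------------------

def sorted_triples(g: CSRGraph):
    src, dst, w = g.edge_triples()
    return sorted(zip(src.tolist(), dst.tolist(), w.tolist()))


def transpose_by_sorting(g: CSRGraph) -> list:
    """Edge triples of the transpose, via naive flip + lexicographic sort."""
    src, dst, w = g.edge_triples()
    return sorted(zip(dst.tolist(), src.tolist(), w.tolist()))


# ---------------------------------------------------------------------------
# exhaustive partition enumeration (Bell numbers)
# ---------------------------------------------------------------------------

def set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    def rec(labels, next_label):
        i = len(labels)
        if i == n:
            yield np.array(labels, dtype=np.int64)
            return
        for lab in range(next_label + 1):
            yield from rec(labels + [lab], max(next_label, lab + 1))
    yield from rec([], 0)


def enumerate_optimum(g: CSRGraph, quality_fn, gamma=1.0):
    """(max Q, argmax labels) by exhaustive enumeration of all partitions."""
    best_q, best_labels = -np.inf, None
    for labels in set_partitions(g.n):
        q = quality_fn(g, Membership.from_labels(labels), gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


# ---------------------------------------------------------------------------
# shared graphs
# ---------------------------------------------------------------------------

@pytest.fixture
def two_triangle_bridge() -> CSRGraph:
    """Two triangles {0,1,2} and {3,4,5} joined by the bridge 2-3."""
    return CSRGraph.from_edges(
        6, [0, 1, 2, 3, 4, 5, 2], [1, 2, 0, 4, 5, 3, 3], directed=False)


@pytest.fixture
def mirrored_pair():
    """An undirected random graph and its mirrored-symmetric digraph twin."""
    rng = np.random.default_rng(3)
    src = rng.integers(0, 40, 200)
    dst = rng.integers(0, 40, 200)
    keep = src != dst
    gu = CSRGraph.from_edges(40, src[keep], dst[keep], directed=False)
    us, ud, uw = gu.edge_triples()    # symmetric storage = mirrored arcs
    gd = CSRGraph.from_edges(40, us, ud, uw, directed=True)
    return gu, gd


def random_graph(rng, n, n_edges, directed, loops=False, weighted=True):
    src = rng.integers(0, n, n_edges)
    dst = rng.integers(0, n, n_edges)
    if not loops:
        keep = src != dst
        src, dst = src[keep], dst[keep]
    w = rng.random(src.shape[0]) + 0.5 if weighted else None
    return CSRGraph.from_edges(n, src, dst, w, directed=directed)
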