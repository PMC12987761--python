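"""Synthetic planted-community benchmark graphs.

Two generators with known ground truth:

* :func:`planted_partition` — equal-size blocks; every edge stays inside its
  block with probability ``1 - mu`` and lands uniformly outside otherwise.
* :func:`lfr_like` — LFR-style graphs: community sizes and node degrees drawn
  from truncated power laws, each node's degree split into internal and
  external stubs by the mixing parameter ``mu``, and stubs wired by
  configuration-model random pairing (self-loops and intra-community
  "external" pairs rejected with a bounded retry budget, then dropped).

The mixing parameter mu is the expected fraction of a node's edge endpoints
that leave its planted community: mu = 0 gives perfectly separated
communities (they are the connected components of the graph) and detection
gets monotonically harder as mu rises toward 1.

Both generators are pure functions of their parameters: the same seed always
yields the same edge multiset.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq

from .graph import (CSRGraph, Membership, read_edge_list, read_membership,
                    write_edge_list, write_membership)

#: reshuffle rounds for rejected stubs before they are dropped
RETRY_ROUNDS = 50


@dataclass(frozen=True)
class GeneratorParams:
    """LFR-style generator configuration.

    ``mu`` is the target mixing fraction; ``tau1``/``tau2`` the degree and
    community-size power-law exponents; degrees live in [~, max_degree] with
    mean ~avg_degree; community sizes in [min_comm, max_comm].
    """

    n: int
    mu: float
    avg_degree: float = 20.0
    max_degree: int = 50
    tau1: float = 2.5
    tau2: float = 1.5
    min_comm: int = 20
    max_comm: int = 100
    directed: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if not (0 < self.min_comm <= self.max_comm <= self.n):
            raise ValueError("require 0 < min_comm <= max_comm <= n")
        if not (1 <= self.avg_degree <= self.max_degree < self.n):
            raise ValueError("require 1 <= avg_degree <= max_degree < n")
        if self.tau1 <= 1 or self.tau2 <= 1:
            raise ValueError("power-law exponents must exceed 1")


@dataclass(frozen=True)
class GroundTruthBundle:
    """A generated graph with its planted partition."""

    graph: CSRGraph
    truth: Membership
    params: GeneratorParams
    realized_mu: float


# ---------------------------------------------------------------------------
# power-law helpers
# ---------------------------------------------------------------------------

def _truncated_power_law(rng, size, tau, xmin, xmax):
    """Continuous samples with pdf ~ x^(-tau) on [xmin, xmax] (inverse CDF)."""
    a = 1.0 - tau
    u = rng.random(size)
    return (xmin ** a + u * (xmax ** a - xmin ** a)) ** (1.0 / a)


def _truncated_power_law_mean(tau, xmin, xmax):
    a = 1.0 - tau
    b = 2.0 - tau
    if abs(b) < 1e-12:
        return a * np.log(xmax / xmin) / (xmax ** a - xmin ** a)
    return (a / b) * (xmax ** b - xmin ** b) / (xmax ** a - xmin ** a)


def _solve_degree_xmin(avg_degree, tau, xmax):
    """Lower cut-off whose truncated power law has the requested mean."""
    lo, hi = 1.0, float(xmax) - 1e-9
    f = lambda x: _truncated_power_law_mean(tau, x, xmax) - avg_degree
    if f(lo) > 0:
        return lo   # even xmin=1 gives a heavier mean; accept the floor
    if f(hi) < 0:
        raise ValueError("avg_degree not achievable under max_degree cut-off")
    return brentq(f, lo, hi)


def _sample_degrees(rng, p: GeneratorParams) -> np.ndarray:
    xmin = _solve_degree_xmin(p.avg_degree, p.tau1, p.max_degree)
    deg = np.rint(_truncated_power_law(rng, p.n, p.tau1, xmin, p.max_degree))
    return np.clip(deg.astype(np.int64), 1, p.max_degree)


def _sample_community_sizes(rng, p: GeneratorParams) -> np.ndarray:
    """Power-law sizes in [min_comm, max_comm] summing exactly to n."""
    sizes: list[int] = []
    total = 0
    while total < p.n:
        s = int(np.rint(_truncated_power_law(rng, 1, p.tau2,
                                             p.min_comm, p.max_comm)[0]))
        s = min(max(s, p.min_comm), p.max_comm)
        if total + s > p.n:
            s = p.n - total     # clip the last community
        sizes.append(s)
        total += s
    sizes = np.asarray(sizes, dtype=np.int64)
    # a clipped last community below min_comm is folded back: shrink it to 0
    # and hand its members one-by-one to communities with spare capacity
    if sizes[-1] < p.min_comm and sizes.shape[0] > 1:
        spare = sizes[-1]
        sizes = sizes[:-1]
        i = 0
        while spare > 0:
            if sizes[i % sizes.shape[0]] < p.max_comm:
                sizes[i % sizes.shape[0]] += 1
                spare -= 1
            i += 1
            if i > 10 * p.n:
                raise ValueError("cannot place all nodes within max_comm bounds")
    return sizes


# ---------------------------------------------------------------------------
# stub pairing
# ---------------------------------------------------------------------------

def _pair_stubs(rng, stubs_a, stubs_b, reject):
    """Pair two stub arrays, rejecting pairs via ``reject(u, v)``.

    Rejected stubs are reshuffled and re-paired for up to ``RETRY_ROUNDS``
    rounds, then dropped: degree sequences are targets, not guarantees.
    Returns (src, dst) arrays.
    """
    src_parts, dst_parts = [], []
    a, b = stubs_a, stubs_b
    for _ in range(RETRY_ROUNDS):
        k = min(a.shape[0], b.shape[0])
        if k == 0:
            break
        a, b = a[:k], b[:k]
        bad = reject(a, b)
        src_parts.append(a[~bad])
        dst_parts.append(b[~bad])
        a, b = a[bad], b[bad]
        if a.shape[0] == 0:
            break
        rng.shuffle(a)
        rng.shuffle(b)
    if src_parts:
        return np.concatenate(src_parts), np.concatenate(dst_parts)
    return np.zeros(0, np.int64), np.zeros(0, np.int64)


def _pair_within(rng, stubs):
    """Undirected pairing of one stub array against itself (no self-loops)."""
    stubs = stubs.copy()
    rng.shuffle(stubs)
    if stubs.shape[0] % 2:
        stubs = stubs[:-1]
    half = stubs.shape[0] // 2
    return _pair_stubs(rng, stubs[:half], stubs[half:], lambda u, v: u == v)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def planted_partition(n: int, k_blocks: int, mu: float, avg_degree: float,
                      directed: bool = False, seed: int = 0) -> GroundTruthBundle:
    """Equal-size planted-partition graph.

    Draws ``round(n*avg_degree/2)`` undirected edges (or ``round(n*avg_degree)``
    arcs): the source is uniform, the target lands inside the source's block
    with probability ``1 - mu`` and uniformly outside otherwise; self-loops
    are redrawn, duplicate pairs weight-sum.
    """
    if n % k_blocks != 0:
        raise ValueError("n must be divisible by k_blocks")
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    block_size = n // k_blocks
    truth = np.repeat(np.arange(k_blocks, dtype=np.int64), block_size)
    n_edges = int(round(n * avg_degree)) if directed else int(round(n * avg_degree / 2))
    src = np.empty(n_edges, dtype=np.int64)
    dst = np.empty(n_edges, dtype=np.int64)
    filled = 0
    while filled < n_edges:
        k = n_edges - filled
        s = rng.integers(0, n, size=k)
        internal = rng.random(k) < (1.0 - mu)
        offset = rng.integers(0, block_size, size=k)
        d_int = truth[s] * block_size + offset
        d_ext = rng.integers(0, n - block_size, size=k)
        d_ext = np.where(d_ext >= truth[s] * block_size, d_ext + block_size, d_ext)
        d = np.where(internal, d_int, d_ext)
        ok = d != s       # redraw self-loops
        kk = int(ok.sum())
        src[filled:filled + kk] = s[ok]
        dst[filled:filled + kk] = d[ok]
        filled += kk
    graph = CSRGraph.from_edges(n, src, dst, directed=directed)
    params = GeneratorParams(n=n, mu=mu, avg_degree=max(avg_degree, 1.0),
                             max_degree=min(n - 1, max(int(avg_degree * 4), 2)),
                             min_comm=1, max_comm=block_size,
                             directed=directed, seed=seed)
    return GroundTruthBundle(graph, Membership(truth, k_blocks), params,
                             _realized_mu(graph, truth))


def _assign_communities(rng, sizes, d_int_target):
    """Capacity-aware node placement: a node with internal degree d needs a
    community of size > d.

    Nodes are placed in descending internal-degree order into a uniformly
    random remaining slot among the communities large enough to host them;
    nodes that no feasible community can absorb fall back to the largest
    community with free slots (their internal degree is capped afterwards).
    """
    k = sizes.shape[0]
    cap = sizes.copy()
    assign = np.empty(d_int_target.shape[0], dtype=np.int64)
    by_size = np.argsort(-sizes, kind="stable")   # communities, largest first
    sorted_sizes = sizes[by_size]
    ptr = 0
    for d in np.unique(d_int_target)[::-1]:
        nodes_d = np.flatnonzero(d_int_target == d)
        rng.shuffle(nodes_d)
        while ptr < k and sorted_sizes[ptr] > d:
            ptr += 1
        prefix = by_size[:ptr]
        slots = np.repeat(prefix, cap[prefix])
        rng.shuffle(slots)
        take = min(slots.shape[0], nodes_d.shape[0])
        assign[nodes_d[:take]] = slots[:take]
        np.subtract.at(cap, slots[:take], 1)
        for v in nodes_d[take:]:    # infeasible leftovers: largest free community
            open_comms = by_size[cap[by_size] > 0]
            assign[v] = open_comms[0]
            cap[open_comms[0]] -= 1
    return assign


def lfr_like(params: GeneratorParams) -> GroundTruthBundle:
    """LFR-style benchmark graph with planted power-law communities."""
    p = params
    rng = np.random.default_rng(p.seed)
    sizes = _sample_community_sizes(rng, p)
    deg = _sample_degrees(rng, p)
    d_int = np.rint((1.0 - p.mu) * deg).astype(np.int64)
    truth = _assign_communities(rng, sizes, d_int)
    # cap any infeasible internal degree at community size - 1; the excess is
    # dropped (degree sequences are targets), never converted to external
    # stubs, so mu = 0 yields exactly zero inter-community edges
    d_int = np.minimum(d_int, sizes[truth] - 1)
    d_ext = deg - np.rint((1.0 - p.mu) * deg).astype(np.int64)

    nodes = np.arange(p.n, dtype=np.int64)
    member_order = np.argsort(truth, kind="stable")
    counts = np.bincount(truth, minlength=sizes.shape[0])
    starts = np.concatenate([[0], np.cumsum(counts)])
    src_parts, dst_parts = [], []
    if p.directed:
        # independent pairing of out-stubs against in-stubs
        for c in range(sizes.shape[0]):
            members = member_order[starts[c]:starts[c + 1]]
            stubs = np.repeat(members, d_int[members])
            out_s, in_s = stubs.copy(), stubs.copy()
            rng.shuffle(out_s)
            rng.shuffle(in_s)
            s, d = _pair_stubs(rng, out_s, in_s, lambda u, v: u == v)
            src_parts.append(s)
            dst_parts.append(d)
        out_e = np.repeat(nodes, d_ext)
        in_e = out_e.copy()
        rng.shuffle(out_e)
        rng.shuffle(in_e)
        s, d = _pair_stubs(rng, out_e, in_e,
                           lambda u, v: (u == v) | (truth[u] == truth[v]))
        src_parts.append(s)
        dst_parts.append(d)
    else:
        for c in range(sizes.shape[0]):
            members = member_order[starts[c]:starts[c + 1]]
            s, d = _pair_within(rng, np.repeat(members, d_int[members]))
            src_parts.append(s)
            dst_parts.append(d)
        ext = np.repeat(nodes, d_ext)
        rng.shuffle(ext)
        if ext.shape[0] % 2:
            ext = ext[:-1]
        half = ext.shape[0] // 2
        s, d = _pair_stubs(rng, ext[:half], ext[half:],
                           lambda u, v: (u == v) | (truth[u] == truth[v]))
        src_parts.append(s)
        dst_parts.append(d)

    src = np.concatenate(src_parts)
    dst = np.concatenate(dst_parts)
    graph = CSRGraph.from_edges(p.n, src, dst, directed=p.directed)
    return GroundTruthBundle(graph, Membership(truth, sizes.shape[0]), p,
                             _realized_mu(graph, truth))


def _realized_mu(graph: CSRGraph, truth: np.ndarray) -> float:
    """Achieved inter-community weight fraction of the generated graph."""
    src, dst, w = graph.edge_triples()
    total = float(w.sum())
    if total == 0:
        return 0.0
    inter = float(w[truth[src] != truth[dst]].sum())
    return inter / total


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_ground_truth(bundle: GroundTruthBundle, dir_path) -> None:
    """Write edges.tsv + truth.tsv + params.json into ``dir_path``."""
    os.makedirs(dir_path, exist_ok=True)
    write_edge_list(os.path.join(dir_path, "edges.tsv"), bundle.graph)
    write_membership(os.path.join(dir_path, "truth.tsv"), bundle.truth)
    payload = asdict(bundle.params)
    payload["realized_mu"] = bundle.realized_mu
    with open(os.path.join(dir_path, "params.json"), "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_ground_truth(dir_path) -> GroundTruthBundle:
    """Inverse of :func:`write_ground_truth`."""
    with open(os.path.join(dir_path, "params.json")) as fh:
        payload = json.load(fh)
    realized = payload.pop("realized_mu")
    params = GeneratorParams(**payload)
    graph = read_edge_list(os.path.join(dir_path, "edges.tsv"),
                           directed=params.directed, n=params.n)
    truth = read_membership(os.path.join(dir_path, "truth.tsv"), n=graph.n)
    return GroundTruthBundle(graph, truth, params, realized)
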