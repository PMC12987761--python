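"""The three Leiden phases and the outer convergence loop.

One pass = local moving -> refinement -> aggregation.  Local moving sweeps
the nodes in a seeded random permutation, repeatedly, moving each node to the
neighboring community with the best strictly positive modularity gain until a
whole sweep moves nothing.  Refinement then splits every community into
well-connected pieces: each node starts as a singleton and may merge, once,
into a piece of the *same* community with strictly positive gain — this is
the step that distinguishes Leiden from Louvain and guarantees connected
communities.  Aggregation collapses each refined piece into a supernode
(intra-piece weight becomes a self-loop) and the next pass runs on the
coarser graph, with supernodes initially assigned the communities their
members held.  Passes repeat until the structure converges: no node moves,
the graph stops shrinking, or the modularity gain falls below ``tol``.

Directed and undirected graphs run through one unified kernel.  For a
directed graph the gain is the Leicht–Newman form with separate out/in rows
(the in-rows come from the counting-scatter transpose).  An undirected graph
is passed with its symmetric rows on both sides, k = strength and m = 2m,
under which the directed gain reduces algebraically to the undirected
Blondel-form gain, so a mirrored-symmetric digraph and its undirected twin
follow identical trajectories from the same seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _kernels
from .graph import CSRGraph, DirectedGraphView, Membership, transpose_csr
from .quality import modularity

logger = logging.getLogger("dirleiden")

#: modularity-gain threshold below which a move is treated as no gain
GAIN_EPS = _kernels.GAIN_EPS


@dataclass(frozen=True)
class ClusterRunResult:
    """Outcome of :func:`run_leiden` on the original node universe."""

    membership: Membership
    q_trace: list[float]
    passes: int
    seed: int
    moved_per_pass: list[int] = field(default_factory=list)

    @property
    def quality(self) -> float:
        return self.q_trace[-1]


def _kernel_arrays(g: CSRGraph, view: DirectedGraphView | None):
    """Unpack the (out, in, k_out, k_in, m_eff, undirected) kernel inputs."""
    if g.directed:
        if view is None:
            view = DirectedGraphView(g, transpose_csr(g))
        o, i = view.out_csr, view.in_csr
        return (o.offsets, o.targets, o.weights, i.offsets, i.targets, i.weights,
                o.out_strength, o.in_strength, g.m, False)
    k = g.strength
    return (g.offsets, g.targets, g.weights, g.offsets, g.targets, g.weights,
            k, k, 2.0 * g.m, True)


def local_move(g: CSRGraph, p: Membership, gamma: float = 1.0,
               rng: np.random.Generator | None = None,
               view: DirectedGraphView | None = None
               ) -> tuple[Membership, int, float]:
    """Greedy best-gain node sweeps until a full sweep moves nothing.

    Returns the compacted membership, the total number of moves, and the
    modularity gain over the input membership.
    """
    rng = rng or np.random.default_rng(0)
    if g.m == 0:
        return Membership.from_labels(p.assign), 0, 0.0
    (oo, ot, ow, io, it, iw, k_out, k_in, m_eff, und) = _kernel_arrays(g, view)
    comm = p.assign.copy()
    ncomm = max(p.n_communities, int(comm.max()) + 1)
    s_out = np.bincount(comm, weights=k_out, minlength=g.n).astype(np.float64)
    s_in = np.bincount(comm, weights=k_in, minlength=g.n).astype(np.float64)
    q_before = modularity(_graph_or_view(g, view), p, gamma)
    total_moved = 0
    while True:
        order = rng.permutation(g.n).astype(np.int64)
        moved = _kernels.local_move_sweep(
            oo, ot, ow, io, it, iw, k_out, k_in, m_eff, gamma, und,
            comm, s_out, s_in, order)
        total_moved += moved
        if moved == 0:
            break
    out = Membership.from_labels(comm)
    q_after = modularity(_graph_or_view(g, view), out, gamma)
    return out, total_moved, q_after - q_before


def _graph_or_view(g: CSRGraph, view: DirectedGraphView | None):
    return view if (g.directed and view is not None) else g


def refine(g: CSRGraph, p: Membership, gamma: float = 1.0,
           rng: np.random.Generator | None = None,
           view: DirectedGraphView | None = None) -> Membership:
    """Split each community of ``p`` into well-connected sub-communities.

    Nodes are visited once in seeded random order; a node still in a
    singleton piece merges into the best positive-gain piece within its own
    community of ``p``; merged nodes are never revisited.  The result always
    refines ``p``.
    """
    rng = rng or np.random.default_rng(0)
    if g.m == 0:
        return Membership.singletons(g.n)
    (oo, ot, ow, io, it, iw, k_out, k_in, m_eff, und) = _kernel_arrays(g, view)
    order = rng.permutation(g.n).astype(np.int64)
    ref = _kernels.refine_sweep(oo, ot, ow, io, it, iw, k_out, k_in,
                                m_eff, gamma, und, p.assign, order)
    return Membership.from_labels(ref)


def aggregate(g: CSRGraph, refined: Membership, p: Membership
              ) -> tuple[CSRGraph, Membership]:
    """Collapse each refined community into a supernode.

    Edge weight between supernodes is the summed weight of original edges
    between their members; intra-supernode weight becomes a self-loop (for
    undirected graphs each internal edge contributes once, preserving both
    total weight ``m`` and supernode strength).  The returned membership
    assigns every supernode the community its members held in ``p``.
    """
    if len(refined) != g.n or len(p) != g.n:
        raise ValueError("membership length does not match the graph")
    # contract: refined must be a refinement of p
    combo = refined.assign * np.int64(p.n_communities) + p.assign
    if np.unique(combo).shape[0] != refined.n_communities:
        raise ValueError("refined membership does not refine the partition")
    k = refined.n_communities
    proj = sp.csr_matrix(
        (np.ones(g.n), (np.arange(g.n), refined.assign)), shape=(g.n, k))
    coarse = (proj.T @ g.to_scipy() @ proj).tocsr()
    coarse.sum_duplicates()
    if not g.directed:
        # stored symmetric entries put 2*w per internal edge and 1*w per
        # internal loop on the diagonal; the supernode loop must carry
        # internal edges once and internal loops once.
        loops = np.bincount(refined.assign, weights=g.self_loop, minlength=k)
        diag = coarse.diagonal()
        coarse.setdiag((diag + loops) / 2.0)
        coarse.eliminate_zeros()
    agg_g = CSRGraph.from_scipy(coarse, directed=g.directed)
    super_comm = np.zeros(k, dtype=np.int64)
    super_comm[refined.assign] = p.assign
    return agg_g, Membership.from_labels(super_comm)


def run_leiden(g: CSRGraph, gamma: float = 1.0, seed: int = 0,
               max_passes: int = 50, tol: float = 1e-10) -> ClusterRunResult:
    """Full Leiden: (local move -> refine -> aggregate) to convergence.

    ``q_trace`` records modularity on the *original* graph after every pass;
    the result membership is composed through all aggregation levels back to
    the original nodes.
    """
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    rng = np.random.default_rng(seed)
    orig = g
    orig_view = None
    if g.directed:
        orig_view = DirectedGraphView(g, transpose_csr(g))
    if g.m == 0:
        p = Membership.singletons(g.n)
        return ClusterRunResult(p, [0.0], 1, seed, [0])

    p_flat = Membership.singletons(g.n)
    q_trace: list[float] = []
    moved_trace: list[int] = []
    q_prev_descent = -np.inf
    passes = 0
    converged = False
    # Each descent runs local_move / refine / aggregate down the hierarchy;
    # full convergence requires restarting from the original graph with the
    # found partition until a whole sweep there moves no node.
    while not converged and passes < max_passes:
        cur_g, cur_view = g, orig_view
        node_map = np.arange(g.n, dtype=np.int64)  # original node -> supernode
        p = p_flat
        descent_moves = 0
        while passes < max_passes:
            passes += 1
            p, moved, _ = local_move(cur_g, p, gamma, rng, view=cur_view)
            descent_moves += moved
            composed = Membership.from_labels(p.assign[node_map])
            q = modularity(_graph_or_view(orig, orig_view), composed, gamma)
            q_trace.append(q)
            moved_trace.append(moved)
            logger.info("pass %d: moved=%d Q=%.6f communities=%d",
                        passes, moved, q, composed.n_communities)
            if p.n_communities == cur_g.n:
                break    # every supernode its own community: nothing to coarsen
            refined = refine(cur_g, p, gamma, rng, view=cur_view)
            agg_g, p_next = aggregate(cur_g, refined, p)
            if agg_g.n == cur_g.n:
                break    # refinement left all singletons: graph stopped shrinking
            node_map = refined.assign[node_map]
            cur_g, p = agg_g, p_next
            cur_view = (DirectedGraphView(cur_g, transpose_csr(cur_g))
                        if cur_g.directed else None)
        p_flat = Membership.from_labels(p.assign[node_map])
        if descent_moves == 0 or q_trace[-1] - q_prev_descent < tol:
            converged = True    # a whole descent moved nothing: fully converged
        q_prev_descent = q_trace[-1]
    return ClusterRunResult(p_flat, q_trace, passes, seed, moved_trace)
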