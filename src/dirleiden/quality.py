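"""Modularity and incremental move gains, undirected and directed.

Undirected modularity (resolution gamma):

    Q = sum_C [ Sigma_in(C) / (2m) - gamma * (Sigma_tot(C) / (2m))**2 ]

with Sigma_in(C) counting each internal edge twice and each internal
self-loop twice (A_ii = 2 * loop weight) and Sigma_tot(C) the summed node
strengths, so that Q(all-in-one, gamma=1) = 0.

Directed modularity follows the Leicht–Newman null model, where the chance of
an arc i -> j is proportional to k_i^out * k_j^in, normalized by m:

    Q = sum_C [ Sigma_in(C) / m - gamma * S_out(C) * S_in(C) / m**2 ]

The move gains are the standard incremental forms.  The undirected insertion
gain is the Blondel form

    dQ = [(Sigma_in + 2 k_{i,in}) / 2m - gamma ((Sigma_tot + k_i) / 2m)^2]
         - [Sigma_in / 2m - gamma (Sigma_tot / 2m)^2 - gamma (k_i / 2m)^2]

evaluated with node i already removed from every aggregate; the net gain of a
move from community A to B is the insertion-gain difference.  The gains omit
the node's own self-loop term, which is identical for every candidate
community and cancels in all net comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import CSRGraph, DirectedGraphView, Membership


@dataclass(frozen=True)
class CommunityAggregates:
    """Per-community sums that the gain formulas consume.

    ``sigma_in``: internal weight (undirected: each internal edge and loop
    twice; directed: each internal arc once).  ``sigma_tot``: undirected
    strength sums (None for directed).  ``s_out``/``s_in``: directed
    out-/in-strength sums (None for undirected).
    """

    sigma_in: np.ndarray
    sigma_tot: np.ndarray | None = None
    s_out: np.ndarray | None = None
    s_in: np.ndarray | None = None

    @property
    def community_count(self) -> int:
        return int(self.sigma_in.shape[0])


def _as_out_in(g) -> tuple[CSRGraph, CSRGraph]:
    if isinstance(g, DirectedGraphView):
        return g.out_csr, g.in_csr
    return g, g


def undirected_aggregates(g: CSRGraph, p: Membership) -> CommunityAggregates:
    if g.directed:
        raise ValueError("undirected_aggregates requires an undirected graph")
    src, dst, w = g.edge_triples()
    a = p.assign
    k = p.n_communities
    internal = a[src] == a[dst]
    # stored entries give each internal non-loop edge twice, loops once;
    # add loops once more so loops count twice (matching k_i).
    sigma_in = np.bincount(a[src[internal]], weights=w[internal], minlength=k)
    loops = src == dst
    sigma_in += np.bincount(a[src[loops]], weights=w[loops], minlength=k)
    sigma_tot = np.bincount(a, weights=g.strength, minlength=k)
    return CommunityAggregates(sigma_in=sigma_in, sigma_tot=sigma_tot)


def directed_aggregates(g, p: Membership) -> CommunityAggregates:
    out_csr, _ = _as_out_in(g)
    src, dst, w = out_csr.edge_triples()
    a = p.assign
    k = p.n_communities
    internal = a[src] == a[dst]
    sigma_in = np.bincount(a[src[internal]], weights=w[internal], minlength=k)
    s_out = np.bincount(a, weights=out_csr.out_strength, minlength=k)
    s_in = np.bincount(a, weights=out_csr.in_strength, minlength=k)
    return CommunityAggregates(sigma_in=sigma_in, s_out=s_out, s_in=s_in)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity_undirected(g: CSRGraph, p: Membership, gamma: float = 1.0) -> float:
    """Newman–Girvan modularity with resolution ``gamma``; 0 for empty graphs."""
    if g.directed:
        raise ValueError("modularity_undirected requires an undirected graph")
    m = g.m
    if m == 0:
        return 0.0
    agg = undirected_aggregates(g, p)
    two_m = 2.0 * m
    return float(np.sum(agg.sigma_in / two_m - gamma * (agg.sigma_tot / two_m) ** 2))


def modularity_directed(g, p: Membership, gamma: float = 1.0) -> float:
    """Leicht–Newman directed modularity; accepts a CSRGraph or a view."""
    out_csr, _ = _as_out_in(g)
    if not out_csr.directed:
        raise ValueError("modularity_directed requires a directed graph")
    m = out_csr.m
    if m == 0:
        return 0.0
    agg = directed_aggregates(out_csr, p)
    return float(np.sum(agg.sigma_in / m - gamma * agg.s_out * agg.s_in / (m * m)))


def modularity(g, p: Membership, gamma: float = 1.0) -> float:
    """Dispatch to the directed or undirected quality function."""
    out_csr, _ = _as_out_in(g)
    if out_csr.directed:
        return modularity_directed(g, p, gamma)
    return modularity_undirected(out_csr, p, gamma)


# ---------------------------------------------------------------------------
# Node -> community link weights
# ---------------------------------------------------------------------------

def node_links_undirected(g: CSRGraph, p: Membership, i: int) -> dict[int, float]:
    """k_{i,in->C}: weight from node ``i`` to each community, self-loop excluded."""
    lo, hi = g.offsets[i], g.offsets[i + 1]
    links: dict[int, float] = {}
    for j, w in zip(g.targets[lo:hi], g.weights[lo:hi]):
        if j == i:
            continue
        c = int(p.assign[j])
        links[c] = links.get(c, 0.0) + float(w)
    return links


def node_links_directed(view: DirectedGraphView, p: Membership, i: int
                        ) -> tuple[dict[int, float], dict[int, float]]:
    """(k_{i,out->C}, k_{i,in->C}) link-weight maps, self-loop excluded."""
    k_out_to = node_links_undirected(view.out_csr, p, i)
    k_in_from = node_links_undirected(view.in_csr, p, i)
    return k_out_to, k_in_from


# ---------------------------------------------------------------------------
# Move gains
# ---------------------------------------------------------------------------

def delta_q_undirected(agg: CommunityAggregates, links: dict[int, float],
                       k_i: float, target: int, gamma: float, m: float) -> float:
    """Gain of inserting a currently-detached node into community ``target``.

    ``agg`` must not include the node (the caller removes it from its old
    community first); ``links`` maps community -> k_{i,in->C}.
    """
    if m == 0:
        raise ValueError("move gain undefined on a graph with m = 0")
    two_m = 2.0 * m
    sigma_in = float(agg.sigma_in[target])
    sigma_tot = float(agg.sigma_tot[target])
    k_to = links.get(target, 0.0)
    joined = (sigma_in + 2.0 * k_to) / two_m - gamma * ((sigma_tot + k_i) / two_m) ** 2
    apart = (sigma_in / two_m - gamma * (sigma_tot / two_m) ** 2
             - gamma * (k_i / two_m) ** 2)
    return joined - apart


def delta_q_directed(agg: CommunityAggregates,
                     links: tuple[dict[int, float], dict[int, float]],
                     k_out: float, k_in: float, target: int,
                     gamma: float, m: float) -> float:
    """Directed insertion gain for a detached node into ``target``.

    dQ = (k_{i,out->C} + k_{i,in->C}) / m
         - gamma * (k_i^out * S_in(C) + k_i^in * S_out(C)) / m**2
    """
    if m == 0:
        raise ValueError("move gain undefined on a graph with m = 0")
    k_out_to, k_in_from = links
    link = k_out_to.get(target, 0.0) + k_in_from.get(target, 0.0)
    null = k_out * float(agg.s_in[target]) + k_in * float(agg.s_out[target])
    return link / m - gamma * null / (m * m)
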