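"""Numba kernels: CSR transposition scatter and the Leiden sweep loops.

All kernels operate on plain int64/float64 arrays so they stay trivially
cacheable.  The local-move and refinement kernels share one gain formula,
the directed (out-strength x in-strength null model) insertion gain

    gain(i -> C) = (k_out_to[C] + k_in_to[C]) / m
                   - gamma * (k_out[i]*S_in[C] + k_in[i]*S_out[C]) / m**2

evaluated with node i removed from every aggregate.  Undirected graphs are
run through the same kernel with the symmetric row arrays passed for both
directions, k = undirected strength and m = 2*m_undirected, under which the
directed gain reduces exactly to the standard undirected Blondel-form gain
(see dirleiden.quality).  Self-loop terms, constant across candidate
communities, are omitted; they cancel in every move comparison.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: gains below this are treated as zero (round-off suppression)
GAIN_EPS = 1e-12


@njit(cache=True)
def transpose_scatter(n, offsets, targets, weights):
    """Counting-scatter CSR transpose: count, prefix-sum, one placement scan."""
    nnz = targets.shape[0]
    t_offsets = np.zeros(n + 1, dtype=np.int64)
    for e in range(nnz):                      # in-degree counts
        t_offsets[targets[e] + 1] += 1
    for v in range(n):                        # exclusive prefix sum
        t_offsets[v + 1] += t_offsets[v]
    cursor = t_offsets[:n].copy()
    t_targets = np.empty(nnz, dtype=np.int64)
    t_weights = np.empty(nnz, dtype=np.float64)
    for u in range(n):                        # single placement scan
        for e in range(offsets[u], offsets[u + 1]):
            v = targets[e]
            pos = cursor[v]
            t_targets[pos] = u
            t_weights[pos] = weights[e]
            cursor[v] = pos + 1
    return t_offsets, t_targets, t_weights


@njit(cache=True)
def local_move_sweep(out_off, out_tgt, out_w, in_off, in_tgt, in_w,
                     k_out, k_in, m, gamma, undirected,
                     comm, s_out, s_in, order):
    """One full node sweep of the local-moving phase; returns moves made.

    ``comm``, ``s_out``, ``s_in`` are updated in place.  Each node in
    ``order`` is lifted out of its community, its per-community link weights
    are accumulated from the out- and in-rows, and it joins the neighboring
    community with the largest strictly positive net gain (lowest community
    id on ties), else returns home.
    """
    n = comm.shape[0]
    k_out_to = np.zeros(n, dtype=np.float64)
    k_in_to = np.zeros(n, dtype=np.float64)
    cand = np.empty(n, dtype=np.int64)
    seen = np.zeros(n, dtype=np.uint8)
    size = np.zeros(n, dtype=np.int64)
    for v in range(n):
        size[comm[v]] += 1
    free = np.empty(n, dtype=np.int64)   # stack of empty community ids
    n_free = 0
    for c in range(n):
        if size[c] == 0:
            free[n_free] = c
            n_free += 1
    m2 = m * m
    moved = 0
    for idx in range(order.shape[0]):
        i = order[idx]
        c_old = comm[i]
        s_out[c_old] -= k_out[i]
        s_in[c_old] -= k_in[i]
        ncand = 0
        for e in range(out_off[i], out_off[i + 1]):
            j = out_tgt[e]
            if j == i:
                continue
            c = comm[j]
            if seen[c] == 0:
                seen[c] = 1
                cand[ncand] = c
                ncand += 1
            k_out_to[c] += out_w[e]
        if not undirected:
            for e in range(in_off[i], in_off[i + 1]):
                j = in_tgt[e]
                if j == i:
                    continue
                c = comm[j]
                if seen[c] == 0:
                    seen[c] = 1
                    cand[ncand] = c
                    ncand += 1
                k_in_to[c] += in_w[e]
        # baseline: gain of re-inserting into the (reduced) home community
        if undirected:
            link_old = 2.0 * k_out_to[c_old]
        else:
            link_old = k_out_to[c_old] + k_in_to[c_old]
        gain_old = link_old / m - gamma * (
            k_out[i] * s_in[c_old] + k_in[i] * s_out[c_old]) / m2
        best_c = c_old
        best_gain = gain_old
        for t in range(ncand):
            c = cand[t]
            if c == c_old:
                continue
            if undirected:
                link = 2.0 * k_out_to[c]
            else:
                link = k_out_to[c] + k_in_to[c]
            gain = link / m - gamma * (
                k_out[i] * s_in[c] + k_in[i] * s_out[c]) / m2
            if gain > best_gain + GAIN_EPS:
                best_c = c
                best_gain = gain
            elif gain > best_gain - GAIN_EPS and c < best_c and gain - gain_old > GAIN_EPS:
                best_c = c
                best_gain = gain
        # an empty community (gain exactly 0) is also a candidate: splitting
        # off improves Q when every occupied option has negative gain
        if n_free > 0 and size[c_old] > 1 and 0.0 > best_gain + GAIN_EPS \
                and 0.0 - gain_old > GAIN_EPS:
            best_c = free[n_free - 1]
            best_gain = 0.0
        if best_c != c_old and best_gain - gain_old > GAIN_EPS:
            comm[i] = best_c
            moved += 1
            size[c_old] -= 1
            if size[best_c] == 0:        # claimed an empty community
                n_free -= 1
            size[best_c] += 1
            if size[c_old] == 0:
                free[n_free] = c_old
                n_free += 1
        c_new = comm[i]
        s_out[c_new] += k_out[i]
        s_in[c_new] += k_in[i]
        for t in range(ncand):
            c = cand[t]
            seen[c] = 0
            k_out_to[c] = 0.0
            k_in_to[c] = 0.0
    return moved


@njit(cache=True)
def refine_sweep(out_off, out_tgt, out_w, in_off, in_tgt, in_w,
                 k_out, k_in, m, gamma, undirected,
                 parent, order):
    """Refinement: split each parent community into well-connected pieces.

    Every node starts as its own refined singleton.  Visiting nodes once in
    ``order``, a node still in a singleton piece may merge into the refined
    piece of a neighbor, provided the neighbor shares its parent community
    and the merge gain is strictly positive; the best such piece wins (lowest
    id on ties).  Nodes in non-singleton pieces are never revisited.
    """
    n = parent.shape[0]
    ref = np.arange(n, dtype=np.int64)
    size = np.ones(n, dtype=np.int64)
    sr_out = k_out.copy()
    sr_in = k_in.copy()
    k_out_to = np.zeros(n, dtype=np.float64)
    k_in_to = np.zeros(n, dtype=np.float64)
    cand = np.empty(n, dtype=np.int64)
    seen = np.zeros(n, dtype=np.uint8)
    m2 = m * m
    for idx in range(order.shape[0]):
        i = order[idx]
        c_own = ref[i]
        if size[c_own] > 1:
            continue
        sr_out[c_own] -= k_out[i]
        sr_in[c_own] -= k_in[i]
        ncand = 0
        for e in range(out_off[i], out_off[i + 1]):
            j = out_tgt[e]
            if j == i or parent[j] != parent[i]:
                continue
            c = ref[j]
            if seen[c] == 0:
                seen[c] = 1
                cand[ncand] = c
                ncand += 1
            k_out_to[c] += out_w[e]
        if not undirected:
            for e in range(in_off[i], in_off[i + 1]):
                j = in_tgt[e]
                if j == i or parent[j] != parent[i]:
                    continue
                c = ref[j]
                if seen[c] == 0:
                    seen[c] = 1
                    cand[ncand] = c
                    ncand += 1
                k_in_to[c] += in_w[e]
        # re-inserting into the emptied singleton has gain exactly 0
        best_c = -1
        best_gain = 0.0
        for t in range(ncand):
            c = cand[t]
            if undirected:
                link = 2.0 * k_out_to[c]
            else:
                link = k_out_to[c] + k_in_to[c]
            gain = link / m - gamma * (
                k_out[i] * sr_in[c] + k_in[i] * sr_out[c]) / m2
            if gain > best_gain + GAIN_EPS:
                best_c = c
                best_gain = gain
            elif best_c >= 0 and gain > best_gain - GAIN_EPS and c < best_c:
                best_c = c
                best_gain = gain
        if best_c >= 0:
            ref[i] = best_c
            size[best_c] += 1
            size[c_own] -= 1
            sr_out[best_c] += k_out[i]
            sr_in[best_c] += k_in[i]
        else:
            sr_out[c_own] += k_out[i]
            sr_in[c_own] += k_in[i]
        for t in range(ncand):
            c = cand[t]
            seen[c] = 0
            k_out_to[c] = 0.0
            k_in_to[c] = 0.0
    return ref
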