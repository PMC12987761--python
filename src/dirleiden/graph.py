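"""Compressed-sparse-row graph container, file I/O and offset-based transposition.

A :class:`CSRGraph` stores a weighted graph in the usual offsets/targets/weights
layout.  Undirected graphs are stored *symmetrically*: every non-loop edge
``{u, v, w}`` appears as both ``(u, v, w)`` and ``(v, u, w)``, while each
self-loop is stored once.  The total weight ``m`` counts every undirected edge
once and every self-loop once; for directed graphs ``m`` is the sum of all arc
weights.

Directed graphs additionally need in-neighbor access.  Rather than flipping
edges into scratch arrays and sorting them (O(E log E) and several extra
buffers), :func:`transpose_csr` builds the transpose with a counting scatter:
count in-degrees, exclusive-prefix-sum them into offsets, then scan the
out-edges once, dropping each ``(u, v, w)`` into its final slot.  No comparison
sort is involved and the within-row order is deterministic — ascending source
id, because the placement scan visits sources in order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._kernels import transpose_scatter


class GraphParseError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


class GraphValidationError(ValueError):
    """Raised when parsed data violates a graph contract (bad ids, weights)."""


# ---------------------------------------------------------------------------
# Membership
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class Membership:
    """Dense node -> community assignment with compact labels.

    ``assign[i]`` is the community of node ``i``; labels are the dense range
    ``0 .. n_communities-1`` and every community is non-empty.
    """

    assign: np.ndarray
    n_communities: int = field(default=-1)

    def __post_init__(self):
        a = np.ascontiguousarray(self.assign, dtype=np.int64)
        object.__setattr__(self, "assign", a)
        if self.n_communities < 0:
            object.__setattr__(
                self, "n_communities", int(a.max()) + 1 if a.size else 0
            )

    @classmethod
    def from_labels(cls, labels) -> "Membership":
        """Build a membership from arbitrary integer labels, compacting them."""
        labels = np.asarray(labels, dtype=np.int64)
        _, compact = np.unique(labels, return_inverse=True)
        k = int(compact.max()) + 1 if compact.size else 0
        return cls(compact.astype(np.int64), k)

    @classmethod
    def singletons(cls, n: int) -> "Membership":
        return cls(np.arange(n, dtype=np.int64), n)

    def __len__(self) -> int:
        return self.assign.shape[0]

    def __eq__(self, other) -> bool:
        return isinstance(other, Membership) and np.array_equal(
            self.assign, other.assign
        )

    def sizes(self) -> np.ndarray:
        return np.bincount(self.assign, minlength=self.n_communities)


# ---------------------------------------------------------------------------
# CSRGraph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSRGraph:
    """Weighted graph in CSR form; see module docstring for storage rules."""

    n: int
    offsets: np.ndarray   # int64, length n+1
    targets: np.ndarray   # int64
    weights: np.ndarray   # float64, all > 0
    directed: bool

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.ascontiguousarray(self.offsets, np.int64))
        object.__setattr__(self, "targets", np.ascontiguousarray(self.targets, np.int64))
        object.__setattr__(self, "weights", np.ascontiguousarray(self.weights, np.float64))
        self._validate()

    def _validate(self) -> None:
        n, off, tgt, w = self.n, self.offsets, self.targets, self.weights
        if n < 0:
            raise GraphValidationError("node count must be non-negative")
        if off.shape[0] != n + 1 or (n >= 0 and (off[0] != 0 or off[-1] != tgt.shape[0])):
            raise GraphValidationError("offsets array is inconsistent with targets")
        if np.any(np.diff(off) < 0):
            raise GraphValidationError("offsets must be non-decreasing")
        if tgt.shape[0] != w.shape[0]:
            raise GraphValidationError("targets and weights lengths differ")
        if tgt.size and (tgt.min() < 0 or tgt.max() >= n):
            raise GraphValidationError("edge target out of range")
        if w.size and w.min() <= 0:
            raise GraphValidationError("edge weights must be strictly positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_edges_stored(self) -> int:
        return int(self.targets.shape[0])

    @property
    def self_loop(self) -> np.ndarray:
        """Per-node self-loop weight (each loop stored once)."""
        src = self.sources()
        mask = src == self.targets
        return np.bincount(src[mask], weights=self.weights[mask],
                           minlength=self.n) if self.n else np.zeros(0)

    @property
    def out_strength(self) -> np.ndarray:
        """Row sums of the stored adjacency (self-loop counted once)."""
        if self.n == 0:
            return np.zeros(0)
        return np.bincount(self.sources(), weights=self.weights, minlength=self.n)

    @property
    def in_strength(self) -> np.ndarray:
        """Column sums of the stored adjacency (self-loop counted once)."""
        if self.n == 0:
            return np.zeros(0)
        return np.bincount(self.targets, weights=self.weights, minlength=self.n)

    @property
    def strength(self) -> np.ndarray:
        """Undirected strength k_i: row sum plus self-loop.

        Self-loops count twice in k_i — the convention under which
        Q(all-in-one-community, gamma=1) = 0 and sum(k) = 2m.
        """
        if self.directed:
            raise ValueError("strength is an undirected quantity; use out/in_strength")
        return self.out_strength + self.self_loop

    @property
    def m(self) -> float:
        """Total edge weight: undirected edges counted once, self-loops once."""
        total = float(self.weights.sum())
        if self.directed:
            return total
        return (total + float(self.self_loop.sum())) / 2.0

    def sources(self) -> np.ndarray:
        """Per-stored-edge source node ids (CSR row expansion)."""
        return np.repeat(np.arange(self.n, dtype=np.int64), np.diff(self.offsets))

    def edge_triples(self):
        """(src, dst, w) arrays of the stored edges, in CSR order."""
        return self.sources(), self.targets.copy(), self.weights.copy()

    def to_scipy(self) -> sp.csr_matrix:
        """The stored adjacency as a scipy CSR matrix (loops once)."""
        return sp.csr_matrix(
            (self.weights, self.targets, self.offsets), shape=(self.n, self.n)
        )

    @classmethod
    def from_edges(cls, n, src, dst, weights=None, *, directed) -> "CSRGraph":
        """Build from parallel edge arrays.

        Duplicate (src, dst) pairs are weight-summed.  In undirected mode each
        input pair is one undirected edge: non-loop pairs are mirrored into
        symmetric storage and counted once in ``m``.
        """
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        w = (np.ones(src.shape[0]) if weights is None
             else np.asarray(weights, dtype=np.float64))
        if src.size and min(src.min(), dst.min()) < 0:
            raise GraphValidationError("negative node id")
        if src.size and max(src.max(), dst.max()) >= n:
            raise GraphValidationError("node id exceeds declared node count")
        if w.size and w.min() <= 0:
            raise GraphValidationError("edge weights must be strictly positive")
        if not directed:
            nonloop = src != dst
            src, dst, w = (np.concatenate([src, dst[nonloop]]),
                           np.concatenate([dst, src[nonloop]]),
                           np.concatenate([w, w[nonloop]]))
        mat = sp.coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
        mat.sum_duplicates()
        return cls(n, mat.indptr.astype(np.int64), mat.indices.astype(np.int64),
                   mat.data.astype(np.float64), directed)

    @classmethod
    def from_scipy(cls, mat, *, directed) -> "CSRGraph":
        """Wrap an already-symmetric (if undirected) scipy sparse matrix."""
        mat = sp.csr_matrix(mat)
        mat.sum_duplicates()
        mat.eliminate_zeros()
        return cls(mat.shape[0], mat.indptr.astype(np.int64),
                   mat.indices.astype(np.int64), mat.data.astype(np.float64),
                   directed)


# ---------------------------------------------------------------------------
# Transposition and the directed view
# ---------------------------------------------------------------------------

def transpose_csr(g: CSRGraph) -> CSRGraph:
    """Edge-reversed CSR via counting scatter — no comparison sort.

    Three linear passes: (1) in-degree counts per node, (2) exclusive prefix
    sum into the transpose offsets, (3) one scan over the out-edges writing
    each (u, v, w) into ``offsets[v]`` plus a running per-row cursor.
    """
    t_off, t_tgt, t_w = transpose_scatter(g.n, g.offsets, g.targets, g.weights)
    return CSRGraph(g.n, t_off, t_tgt, t_w, g.directed)


@dataclass(frozen=True)
class DirectedGraphView:
    """A directed graph with both out-neighbor and in-neighbor CSR access."""

    out_csr: CSRGraph
    in_csr: CSRGraph

    @property
    def n(self) -> int:
        return self.out_csr.n

    @property
    def m(self) -> float:
        return self.out_csr.m


def build_directed_view(g: CSRGraph) -> DirectedGraphView:
    """Pair a directed graph with its counting-scatter transpose."""
    if not g.directed:
        raise ValueError("build_directed_view requires a directed graph; "
                         "undirected CSR storage is already symmetric")
    return DirectedGraphView(out_csr=g, in_csr=transpose_csr(g))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_edge_list(path, *, directed: bool, weighted: bool | None = None,
                   one_based: bool = False, n: int | None = None) -> CSRGraph:
    """Read a whitespace-separated ``src dst [weight]`` edge list.

    Lines starting with ``#`` are comments; blank lines are skipped.  A
    missing weight column means weight 1.  Duplicate (src, dst) pairs are
    weight-summed.  ``n`` is one more than the largest node id seen (after
    the optional 1-based shift), so isolated trailing nodes must appear as
    endpoints somewhere to be counted.
    """
    srcs, dsts, ws = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphParseError(
                    f"{path}:{lineno}: expected 'src dst [weight]', got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError as exc:
                raise GraphParseError(f"{path}:{lineno}: {exc}") from None
            if weighted is False:
                w = 1.0
            if one_based:
                u, v = u - 1, v - 1
            if u < 0 or v < 0:
                raise GraphValidationError(
                    f"{path}:{lineno}: negative node id after shift")
            if w <= 0:
                raise GraphValidationError(
                    f"{path}:{lineno}: non-positive weight {w}")
            srcs.append(u)
            dsts.append(v)
            ws.append(w)
    n_seen = max(1 + max(max(srcs, default=-1), max(dsts, default=-1)), 0)
    n = n_seen if n is None else max(n, n_seen)
    return CSRGraph.from_edges(
        n, np.array(srcs, dtype=np.int64), np.array(dsts, dtype=np.int64),
        np.array(ws), directed=directed)


def read_mtx(path, *, directed: bool | None = None) -> CSRGraph:
    """Read a MatrixMarket coordinate file (real or pattern).

    ``symmetric`` storage maps to an undirected graph and ``general`` to a
    directed one unless ``directed`` overrides the inference; a general file
    read as undirected is symmetrized.
    """
    from scipy.io import mminfo, mmread

    rows, cols, _entries, fmt, _field, symmetry = mminfo(path)
    if fmt != "coordinate":
        raise GraphParseError(f"{path}: only coordinate MatrixMarket is supported")
    n = max(rows, cols)
    mat = mmread(path).tocoo()  # scipy expands symmetric storage in-place
    if mat.data.size and mat.data.min() <= 0:
        raise GraphValidationError(f"{path}: non-positive weight in matrix")
    if symmetry != "general":
        if directed:
            raise GraphParseError(
                f"{path}: symmetric MatrixMarket cannot be read as directed")
        # off-diagonals are already mirrored; wrap the expanded matrix directly
        return CSRGraph.from_scipy(sp.coo_matrix(
            (mat.data, (mat.row, mat.col)), shape=(n, n)), directed=False)
    if directed is None:
        directed = True
    return CSRGraph.from_edges(n, mat.row.astype(np.int64),
                               mat.col.astype(np.int64),
                               mat.data.astype(np.float64), directed=directed)


def read_graph(path, *, directed: bool, weighted: bool | None = None,
               one_based: bool = False) -> CSRGraph:
    """Dispatch on extension: ``.mtx`` -> MatrixMarket, else edge-list TSV."""
    if os.fspath(path).endswith(".mtx"):
        return read_mtx(path, directed=directed)
    return read_edge_list(path, directed=directed, weighted=weighted,
                          one_based=one_based)


def write_edge_list(path, g: CSRGraph) -> None:
    """Write ``src dst weight`` TSV; undirected edges are written once (u<=v)."""
    src, dst, w = g.edge_triples()
    if not g.directed:
        keep = src <= dst
        src, dst, w = src[keep], dst[keep], w[keep]
    with open(path, "w") as fh:
        for u, v, ww in zip(src, dst, w):
            fh.write(f"{u}\t{v}\t{ww:.17g}\n")


def write_membership(path, membership: Membership) -> None:
    """Write ``node_id<TAB>community_id`` lines, 0-based, sorted by node id."""
    with open(path, "w") as fh:
        for node, comm in enumerate(membership.assign):
            fh.write(f"{node}\t{comm}\n")


def read_membership(path, *, n: int | None = None) -> Membership:
    """Read a membership TSV written by :func:`write_membership`."""
    nodes, comms = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphParseError(f"{path}:{lineno}: expected 'node community'")
            nodes.append(int(parts[0]))
            comms.append(int(parts[1]))
    nodes = np.asarray(nodes, dtype=np.int64)
    comms = np.asarray(comms, dtype=np.int64)
    size = n if n is not None else (int(nodes.max()) + 1 if nodes.size else 0)
    assign = np.full(size, -1, dtype=np.int64)
    assign[nodes] = comms
    if np.any(assign < 0):
        raise GraphValidationError(f"{path}: membership does not cover all nodes")
    return Membership(assign)
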